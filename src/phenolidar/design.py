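"""Field-trial designs: plot layouts, genotype allocation, plot rectangles.

Two layouts are supported, mirroring common wheat-trial practice:

* ``rcbd`` — randomized complete block design: every genotype appears once per
  replicate block, blocks occupy contiguous bands of the field grid.
* ``partial_rep`` — partial-replicate design: a fixed plot budget is split over
  genotypes so that only a subset is replicated, giving a fractional mean
  replication (e.g. 98 genotypes in 240 plots average 2.45 replicates).

Plot positions live on an integer (row, col) field grid; each plot carries a
rectangle in field coordinates (metres) delimiting the *sampled* section of
the plot — the area destructively harvested and scanned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PlotRect",
    "PlotAssignment",
    "TrialDesign",
    "simulate_design",
    "read_design",
    "write_design",
]


@dataclass(frozen=True)
class PlotRect:
    """Sampled rectangle of one plot, in field coordinates (metres).

    ``n_rows × row_spacing × sampled_length`` is the ground area harvested
    for biomass and matched by the LiDAR segmentation.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    n_rows: int
    row_spacing: float
    sampled_length: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate rectangle: x=[{self.x_min}, {self.x_max}], "
                f"y=[{self.y_min}, {self.y_max}]"
            )
        if self.n_rows < 1 or self.row_spacing <= 0 or self.sampled_length <= 0:
            raise ValidationError("n_rows, row_spacing and sampled_length must be positive")

    @property
    def sampled_area(self) -> float:
        """Harvested ground area in m²."""
        return self.n_rows * self.row_spacing * self.sampled_length

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def length(self) -> float:
        return self.y_max - self.y_min


@dataclass(frozen=True)
class PlotAssignment:
    plot_id: str
    genotype: str
    replicate: int
    row: int
    col: int
    rect: PlotRect
    seed_density: float = 250.0


@dataclass
class TrialDesign:
    plots: tuple[PlotAssignment, ...]
    design_type: str  # "rcbd" | "partial_rep"
    rep_range: tuple[int, int] | None = None
    field_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.plots = tuple(self.plots)
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise ValidationError("plot_ids are not unique")
        pos = [(p.row, p.col) for p in self.plots]
        if len(set(pos)) != len(pos):
            raise ValidationError("(row, col) positions are not unique")
        if self.design_type not in ("rcbd", "partial_rep"):
            raise ValidationError(f"unknown design_type {self.design_type!r}")
        reps = self.replication
        if self.design_type == "rcbd" and reps.nunique() != 1:
            raise ValidationError("rcbd requires equal replication for every genotype")
        if self.design_type == "partial_rep" and self.rep_range is not None:
            lo, hi = self.rep_range
            if not ((reps >= lo) & (reps <= hi)).all():
                raise ValidationError(
                    f"partial_rep replication outside stated range [{lo}, {hi}]"
                )

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(sorted({p.genotype for p in self.plots}))

    @property
    def replication(self) -> pd.Series:
        """Plots per genotype."""
        return pd.Series([p.genotype for p in self.plots]).value_counts().sort_index()

    @property
    def mean_replication(self) -> float:
        """Arithmetic mean number of plots per genotype."""
        return float(self.replication.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plots:
            r = p.rect
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "genotype": p.genotype,
                    "replicate": p.replicate,
                    "row": p.row,
                    "col": p.col,
                    "x_min": r.x_min,
                    "x_max": r.x_max,
                    "y_min": r.y_min,
                    "y_max": r.y_max,
                    "n_rows": r.n_rows,
                    "row_spacing": r.row_spacing,
                    "sampled_length": r.sampled_length,
                    "seed_density": p.seed_density,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, design_type: str = "partial_rep") -> "TrialDesign":
        plots = []
        for _, r in df.iterrows():
            rect = PlotRect(
                float(r.x_min), float(r.x_max), float(r.y_min), float(r.y_max),
                int(r.n_rows), float(r.row_spacing), float(r.sampled_length),
            )
            plots.append(
                PlotAssignment(
                    str(r.plot_id), str(r.genotype), int(r.replicate),
                    int(r.row), int(r.col), rect,
                    float(r.get("seed_density", 250.0)),
                )
            )
        return cls(tuple(plots), design_type)


@dataclass(frozen=True)
class PlotGeometry:
    """Geometry of the sampled section of each plot.

    Defaults correspond to a 6-row sample at 0.18 m row spacing over 1.0 m
    of row length (1.08 m² sampled area); ``plot_length`` and ``path`` set
    the field pitch between sampled rectangles.
    """

    n_rows: int = 6
    row_spacing: float = 0.18
    sampled_length: float = 1.0
    plot_length: float = 6.0
    path: float = 0.4


def _partial_rep_counts(
    n_genotypes: int, n_plots: int, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    if lo < 1 or hi < lo:
        raise ValidationError(f"invalid replication range [{lo}, {hi}]")
    if not (n_genotypes * lo <= n_plots <= n_genotypes * hi):
        raise ValidationError(
            f"{n_plots} plots cannot hold {n_genotypes} genotypes with "
            f"replication in [{lo}, {hi}]"
        )
    base, extra = divmod(n_plots, n_genotypes)
    counts = np.full(n_genotypes, base, dtype=int)
    if extra:
        counts[rng.choice(n_genotypes, size=extra, replace=False)] += 1
    # spread replication across [lo, hi] by mean-preserving transfers
    for _ in range(n_genotypes // 3):
        donors = np.flatnonzero(counts > lo)
        receivers = np.flatnonzero(counts < hi)
        if donors.size == 0 or receivers.size == 0:
            break
        d = int(rng.choice(donors))
        r = int(rng.choice(receivers))
        if d != r:
            counts[d] -= 1
            counts[r] += 1
    return counts


def simulate_design(
    n_genotypes: int,
    design_type: str,
    replication_spec,
    field_shape: tuple[int, int] | None = None,
    rng_seed: int = 0,
    *,
    geometry: PlotGeometry = PlotGeometry(),
    seed_density: float = 250.0,
) -> TrialDesign:
    """Generate a randomized trial layout.

    Parameters
    ----------
    replication_spec
        For ``rcbd``: the integer number of complete replicates. For
        ``partial_rep``: ``(n_plots, min_rep, max_rep)`` — the total plot
        budget and the allowed per-genotype replication range.
    field_shape
        ``(rows, cols)`` of the plot grid; defaults to a near-square grid
        holding exactly the requested plots.

    The same ``rng_seed`` always yields an identical design.
    """
    if n_genotypes < 2:
        raise ValidationError("a trial needs at least 2 genotypes")
    rng = np.random.default_rng(rng_seed)

    if design_type == "rcbd":
        n_reps = int(replication_spec)
        if n_reps < 1:
            raise ValidationError("rcbd needs at least 1 replicate")
        n_plots = n_genotypes * n_reps
        rep_range = None
    elif design_type == "partial_rep":
        n_plots, lo, hi = (int(v) for v in replication_spec)
        counts = _partial_rep_counts(n_genotypes, n_plots, lo, hi, rng)
        rep_range = (lo, hi)
    else:
        raise ValidationError(f"unknown design_type {design_type!r}")

    if field_shape is None:
        cols = int(math.ceil(math.sqrt(n_plots)))
        rows = int(math.ceil(n_plots / cols))
        field_shape = (rows, cols)
    f_rows, f_cols = field_shape
    if f_rows * f_cols < n_plots:
        raise ValidationError(
            f"field of {f_rows}×{f_cols} plots cannot hold {n_plots} plots"
        )

    genotypes = [f"G{i + 1:03d}" for i in range(n_genotypes)]

    # genotype sequence over plot positions (row-major field order)
    if design_type == "rcbd":
        seq: list[str] = []
        for _ in range(n_reps):
            seq.extend(np.array(genotypes)[rng.permutation(n_genotypes)])
    else:
        pool = np.repeat(genotypes, counts)
        seq = list(pool[rng.permutation(n_plots)])

    g = geometry
    width = g.n_rows * g.row_spacing
    pitch_x = width + g.path
    pitch_y = g.plot_length + g.path
    y_off = (g.plot_length - g.sampled_length) / 2.0

    rep_counter: dict[str, int] = {}
    plots = []
    for i, geno in enumerate(seq):
        row, col = divmod(i, f_cols)
        rep_counter[geno] = rep_counter.get(geno, 0) + 1
        rect = PlotRect(
            x_min=col * pitch_x,
            x_max=col * pitch_x + width,
            y_min=row * pitch_y + y_off,
            y_max=row * pitch_y + y_off + g.sampled_length,
            n_rows=g.n_rows,
            row_spacing=g.row_spacing,
            sampled_length=g.sampled_length,
        )
        plots.append(
            PlotAssignment(
                plot_id=f"P{i + 1:03d}",
                genotype=geno,
                replicate=rep_counter[geno],
                row=row + 1,
                col=col + 1,
                rect=rect,
                seed_density=seed_density,
            )
        )
    return TrialDesign(tuple(plots), design_type, rep_range, field_shape)


def write_design(design: TrialDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path, design_type: str = "partial_rep") -> TrialDesign:
    return TrialDesign.from_frame(pd.read_csv(path, comment="#"), design_type)
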