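"""Event-wise random-effects analysis of plot trait values.

The model for one trait at one sampling event is

    y = Xβ + Z_g u_g + Z_row u_row + Z_col u_col + ε,

with independent random intercepts for genotype, field row and field column
(u_k ~ N(0, σ²_k I)) and i.i.d. residuals. X is an intercept, optionally
augmented with a fixed second-order polynomial in the centred (row, col)
coordinates as a smooth spatial trend. Variance components are estimated by
REML via EM iterations; negative estimates cannot occur (the EM update is a
posterior expectation of a non-negative quantity) and components that
collapse numerically are pinned to zero.

From the fitted components:

* repeatability (broad-sense heritability on a genotype-mean basis)
  ρ = σ²_g / (σ²_g + σ²_ε / nrep), with nrep the mean genotype replication;
* BLUPs of genotype effects û_g = σ²_g Z_g' P y (shrunken genotype means);
* Pearson correlations between BLUP vectors with two-sided t-test p-values
  and significance stars (**** <0.0001, *** <0.001, ** <0.01, * <0.05);
* intraclass correlations between two sampling events (BLUP correlation);
* raw-data (non-spatially-corrected) least-squares regression of AGB on an
  index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve

from .errors import PhenolidarError, ValidationError

__all__ = [
    "VarianceDecomposition",
    "CorrelationResult",
    "RegressionResult",
    "fit_random_effects",
    "repeatability",
    "significance_stars",
    "correlate_blups",
    "icc_between_events",
    "regress_raw",
]


def repeatability(sigma2_g: float, sigma2_e: float, nrep: float) -> float:
    """ρ = σ²_g / (σ²_g + σ²_ε / nrep), clamped to [0, 1].

    Defined as 0 when σ²_g = 0 (including the 0/0 case).
    """
    if nrep <= 0:
        raise ValidationError("nrep must be > 0")
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValidationError("variance components must be >= 0")
    if sigma2_g == 0.0:
        return 0.0
    rho = sigma2_g / (sigma2_g + sigma2_e / nrep)
    return float(min(max(rho, 0.0), 1.0))


@dataclass
class VarianceDecomposition:
    sigma2_g: float
    sigma2_row: float
    sigma2_col: float
    sigma2_e: float
    nrep: float
    blups: pd.Series
    converged: bool
    n_iter: int
    degenerate: bool = False
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None

    @property
    def rho(self) -> float:
        return repeatability(self.sigma2_g, self.sigma2_e, self.nrep)


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(labels, sort=True)
    Z = np.zeros((len(codes), len(uniques)))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z, list(uniques)


def _trend_columns(row: np.ndarray, col: np.ndarray) -> np.ndarray:
    r = (row - row.mean()) / max(row.std(), 1e-12)
    c = (col - col.mean()) / max(col.std(), 1e-12)
    return np.column_stack([r, c, r * r, c * c, r * c])


def fit_random_effects(
    data: pd.DataFrame,
    *,
    value_col: str = "value",
    factors: tuple[str, ...] = ("genotype", "row", "col"),
    include_trend: bool = False,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    nrep_method: str = "arithmetic",
) -> VarianceDecomposition:
    """REML variance components and genotype BLUPs for one event × trait.

    ``data`` needs one row per plot with columns ``genotype`` (and ``row``,
    ``col`` when those factors are fitted) and the trait value. ``factors``
    selects which random intercepts enter the model; ``genotype`` must be
    among them. EM iterations run until the largest relative change of any
    component (scaled by the phenotypic variance) falls below ``tol``.

    A degenerate fit (fewer than two genotypes, or identical observations)
    returns all-zero components with ``degenerate=True`` rather than
    raising.
    """
    if "genotype" not in factors:
        raise ValidationError("'genotype' must be one of the fitted factors")
    for f in factors:
        if f not in data.columns:
            raise ValidationError(f"data lacks column {f!r}")
    data = data.dropna(subset=[value_col])  # listwise deletion, no imputation
    y = data[value_col].to_numpy(dtype=float)
    n = y.size
    genotypes = sorted(pd.unique(data["genotype"]))
    counts = data["genotype"].value_counts()
    if nrep_method == "arithmetic":
        nrep = float(counts.mean()) if len(counts) else 1.0
    elif nrep_method == "harmonic":
        nrep = float(len(counts) / (1.0 / counts).sum()) if len(counts) else 1.0
    else:
        raise ValidationError(f"unknown nrep_method {nrep_method!r}")

    var_y = float(np.var(y)) if n else 0.0
    # numerically constant responses (relative spread below fp precision)
    # are degenerate: no variance to decompose
    degenerate_scale = 1e-20 * (1.0 + float(np.mean(y)) ** 2) if n else 0.0
    if len(genotypes) < 2 or var_y <= degenerate_scale or n < 3:
        blups = pd.Series(0.0, index=genotypes, name="blup")
        return VarianceDecomposition(
            0.0, 0.0, 0.0, 0.0, max(nrep, 1.0), blups,
            converged=True, n_iter=0, degenerate=True,
            residuals=np.zeros(n), fitted=np.full(n, y.mean() if n else 0.0),
        )

    Zs, levels = [], []
    for f in factors:
        Z, lv = _indicator(data[f])
        Zs.append(Z)
        levels.append(lv)
    G = [Z @ Z.T for Z in Zs]
    q = np.array([Z.shape[1] for Z in Zs], dtype=float)

    X = np.ones((n, 1))
    if include_trend:
        if not {"row", "col"}.issubset(data.columns):
            raise ValidationError("trend requires 'row' and 'col' columns")
        X = np.hstack(
            [X, _trend_columns(data["row"].to_numpy(float), data["col"].to_numpy(float))]
        )

    K = len(Zs)
    s2 = np.full(K + 1, var_y / (K + 1))  # [factors..., residual]
    I = np.eye(n)
    floor = 1e-10 * var_y
    converged = False
    it = 0
    history: list[np.ndarray] = []  # snapshots every 10 iters for Aitken
    for it in range(1, max_iter + 1):
        V = s2[K] * I
        for k in range(K):
            if s2[k] > 0:
                V += s2[k] * G[k]
        cho = cho_factor(V, lower=True)
        Vinv = cho_solve(cho, I)
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        W = np.linalg.solve(XtVinvX, VinvX.T)  # (p, n)
        P = Vinv - VinvX @ W
        Py = P @ y

        new = s2.copy()
        for k in range(K):
            if s2[k] == 0.0:
                continue
            u = s2[k] * (Zs[k].T @ Py)
            tr = float(np.einsum("ij,ji->", P, G[k]))
            new[k] = (u @ u + s2[k] * q[k] - s2[k] ** 2 * tr) / q[k]
        e = s2[K] * Py
        new[K] = (e @ e + s2[K] * n - s2[K] ** 2 * np.trace(P)) / n

        delta = float(np.max(np.abs(new - s2))) / var_y
        s2 = new
        s2[:K][s2[:K] < floor] = 0.0  # pin collapsed components
        s2[K] = max(s2[K], floor)
        if delta < tol:
            converged = True
            break
        # Aitken Δ² acceleration on 10-iteration subsampled sequences: EM
        # approaches each component's REML value (or the zero boundary)
        # geometrically, so extrapolating the limit skips the slow tail.
        if it % 10 == 0:
            history.append(s2.copy())
            if len(history) >= 3:
                a, b, c = history[-3], history[-2], history[-1]
                jumped = False
                for k in range(K + 1):
                    d2 = c[k] - 2.0 * b[k] + a[k]
                    monotone = (a[k] > b[k] > c[k] > 0.0) or (0.0 < a[k] < b[k] < c[k])
                    if monotone and abs(d2) > 1e-300:
                        lim = a[k] - (b[k] - a[k]) ** 2 / d2
                        if k < K and lim <= floor:
                            s2[k] = 0.0
                            jumped = True
                        elif floor < lim < 4.0 * var_y and abs(lim - c[k]) < var_y:
                            s2[k] = lim
                            jumped = True
                if jumped:
                    history.clear()
                else:
                    history = history[-2:]

    # final mixed-model solve at the converged components
    V = s2[K] * I
    for k in range(K):
        if s2[k] > 0:
            V += s2[k] * G[k]
    cho = cho_factor(V, lower=True)
    Vinv = cho_solve(cho, I)
    VinvX = Vinv @ X
    W = np.linalg.solve(X.T @ VinvX, VinvX.T)
    beta = W @ y
    P = Vinv - VinvX @ W
    Py = P @ y

    gi = factors.index("genotype")
    u_g = s2[gi] * (Zs[gi].T @ Py)
    blups = pd.Series(u_g, index=levels[gi], name="blup")

    fitted = X @ beta
    for k in range(K):
        if s2[k] > 0:
            fitted = fitted + Zs[k] @ (s2[k] * (Zs[k].T @ Py))
    residuals = y - fitted

    comp = {f: 0.0 for f in ("genotype", "row", "col")}
    for f, v in zip(factors, s2[:K]):
        comp[f] = float(v)
    return VarianceDecomposition(
        sigma2_g=comp["genotype"],
        sigma2_row=comp["row"],
        sigma2_col=comp["col"],
        sigma2_e=float(s2[K]),
        nrep=nrep,
        blups=blups,
        converged=converged,
        n_iter=it,
        residuals=residuals,
        fitted=fitted,
    )


_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    stars: str = field(default="")

    @classmethod
    def from_pairs(cls, a: np.ndarray, b: np.ndarray) -> "CorrelationResult":
        if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
            # a constant BLUP vector (zero genotype variance) carries no
            # ranking information; the correlation is undefined
            return cls(float("nan"), 1.0, len(a), "")
        r, p = sps.pearsonr(a, b)
        return cls(float(r), float(p), len(a), significance_stars(float(p)))


def correlate_blups(blups_a: pd.Series, blups_b: pd.Series) -> CorrelationResult:
    """Pearson correlation of two BLUP vectors over their shared genotypes.

    The p-value is two-sided from the t distribution with n − 2 df, and the
    star annotation follows the <0.0001/<0.001/<0.01/<0.05 thresholds.
    """
    shared = blups_a.index.intersection(blups_b.index)
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared genotypes for a correlation, got {len(shared)}"
        )
    return CorrelationResult.from_pairs(
        blups_a.loc[shared].to_numpy(float), blups_b.loc[shared].to_numpy(float)
    )


def icc_between_events(
    traits: pd.DataFrame,
    trait: str,
    event_a,
    event_b,
    **fit_kwargs,
) -> CorrelationResult:
    """Intraclass correlation of a trait between two sampling events.

    Fits the random-effects model separately at each event and correlates
    the genotype BLUPs. ``traits`` is the long table (plot_id, genotype,
    date, trait, value, plus row/col when those factors are fitted).
    """
    sub = traits[traits["trait"] == trait]
    if sub.empty:
        raise PhenolidarError(f"no rows for trait {trait!r}")
    dates = pd.to_datetime(sub["date"])
    blups = []
    for event in (event_a, event_b):
        mask = dates == pd.Timestamp(event)
        if not mask.any():
            raise PhenolidarError(
                f"no sampling event on {pd.Timestamp(event).date()} for {trait!r}"
            )
        blups.append(fit_random_effects(sub[mask], **fit_kwargs).blups)
    return correlate_blups(*blups)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def regress_raw(agb, index) -> RegressionResult:
    """OLS of plot-level AGB on a LiDAR index (raw, non-spatially-corrected)."""
    agb = np.asarray(agb, dtype=float)
    index = np.asarray(index, dtype=float)
    if agb.shape != index.shape or agb.ndim != 1:
        raise ValidationError("agb and index must be equal-length 1-D sequences")
    if agb.size < 3:
        raise ValidationError("need >= 3 paired plots")
    if np.var(index) == 0.0:
        raise ValidationError("index has zero variance; regression undefined")
    res = sps.linregress(index, agb)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue),
        float(res.pvalue), agb.size,
    )
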