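"""The 13-model space, Bayesian model selection/averaging, and the
cross-method agreement statistics (Pearson, robust regression, bootstrap).

All models share the same skeleton: auditory inputs V and NV drive STS
directly; the intrinsic network holds the four inter-regional connections
STS<->TPJ and STS<->IFG plus the three self-connections.  The thirteen
hypotheses differ only in which inter-regional connection carries a
modulatory effect of V, NV or both:

    model_1        no modulation
    models 2-5     V on [STS->TPJ, TPJ->STS, STS->IFG, IFG->STS]
    models 6-9     NV on the same connections in the same order
    models 10-13   both V and NV on the same connection

(The published constraint set fixes the shared structure, the count, the
parameter census and model 8's identity -- NV on STS->IFG; the remaining
ordering is this package's documented enumeration.)  Totals across the
space: 91 intrinsic parameters, 26 driving inputs, 8 V- and 8
NV-modulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generative import DCMSpec, REGIONS, INPUTS

__all__ = [
    "ModelSpace",
    "BMSResult",
    "BMAResult",
    "build_model_space",
    "bms",
    "bma",
    "pearson",
    "robust_regression",
    "bootstrap_regression",
]

# inter-regional connections in the enumeration order used for modulation
MODULATION_ORDER = (
    ("STS", "TPJ"),  # STS->TPJ
    ("TPJ", "STS"),
    ("STS", "IFG"),
    ("IFG", "STS"),
)


@dataclass
class ModelSpace:
    models: list
    provenance: str = (
        "Constrained reconstruction: shared A-skeleton (STS<->TPJ, STS<->IFG, "
        "3 self-connections), V and NV driving STS in every model; "
        "modulation assignment enumerated as 1 none / 2-5 V / 6-9 NV / "
        "10-13 both over [STS->TPJ, TPJ->STS, STS->IFG, IFG->STS]."
    )

    def __len__(self):
        return len(self.models)

    def __getitem__(self, i):
        return self.models[i]

    def parameter_census(self) -> dict:
        """Counts across the space: intrinsic (A), inputs (C), V- and
        NV-modulations."""
        n_a = sum(int(m.A_mask.sum()) for m in self.models)
        n_c = sum(int(m.C_mask.sum()) for m in self.models)
        iv = INPUTS.index("V")
        inv = INPUTS.index("NV")
        n_bv = sum(int(m.B_mask[iv].sum()) for m in self.models)
        n_bnv = sum(int(m.B_mask[inv].sum()) for m in self.models)
        return {"A": n_a, "C": n_c, "B_V": n_bv, "B_NV": n_bnv}

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "provenance": self.provenance,
                "models": [m.to_json() for m in self.models],
            },
            indent=2,
        )


def _base_spec(name: str) -> DCMSpec:
    n = len(REGIONS)
    sts = REGIONS.index("STS")
    A = -0.5 * np.eye(n)
    A_mask = np.eye(n, dtype=bool)
    for src, dst in MODULATION_ORDER:
        A_mask[REGIONS.index(dst), REGIONS.index(src)] = True
    C_mask = np.zeros((n, len(INPUTS)), dtype=bool)
    C_mask[sts, :] = True
    return DCMSpec(
        A=A,
        A_mask=A_mask,
        C_mask=C_mask,
        B_mask=np.zeros((len(INPUTS), n, n), dtype=bool),
        name=name,
    )


def build_model_space() -> ModelSpace:
    """Enumerate the 13 alternative models (see module docstring)."""
    models = [_base_spec("model_1")]
    for block, inputs in enumerate((("V",), ("NV",), ("V", "NV"))):
        for conn_idx, (src, dst) in enumerate(MODULATION_ORDER):
            spec = _base_spec(f"model_{1 + block * 4 + conn_idx + 1}")
            for inp in inputs:
                spec.B_mask[INPUTS.index(inp), REGIONS.index(dst), REGIONS.index(src)] = True
            models.append(spec)
    return ModelSpace(models)


# ---------------------------------------------------------------------------
# Bayesian model selection / averaging
# ---------------------------------------------------------------------------


@dataclass
class BMSResult:
    """Fixed-effects model comparison from free energies."""

    model_names: list
    free_energy: np.ndarray
    probability: np.ndarray
    best_index: int

    @property
    def best_name(self) -> str:
        return self.model_names[self.best_index]

    def log_evidence_differences(self) -> np.ndarray:
        return self.free_energy - self.free_energy.max()


def bms(fits, model_names=None) -> BMSResult:
    """Fixed-effects Bayesian model selection: p(m) propto exp(F_m).

    ``fits`` is a sequence of PosteriorFit (or bare free energies), one per
    model over the same data.  Ties resolve to the lowest index.
    """
    F = np.array(
        [f.free_energy if hasattr(f, "free_energy") else float(f) for f in fits]
    )
    if np.any(~np.isfinite(F)):
        missing = int(np.nonzero(~np.isfinite(F))[0][0])
        raise ValueError(f"missing or non-finite free energy for model index {missing}")
    if model_names is None:
        model_names = [f"model_{i + 1}" for i in range(len(F))]
    w = np.exp(F - F.max())
    prob = w / w.sum()
    best = int(np.argmax(F))  # argmax returns the lowest index on ties
    return BMSResult(list(model_names), F, prob, best)


@dataclass
class BMAResult:
    """Model-averaged posterior mean/variance per named parameter."""

    parameter_names: list
    mean: np.ndarray
    variance: np.ndarray

    def as_dict(self) -> dict:
        return {
            n: (float(m), float(v))
            for n, m, v in zip(self.parameter_names, self.mean, self.variance)
        }


def bma(fits, bms_result: BMSResult) -> BMAResult:
    """Bayesian model averaging as Gaussian-mixture moments.

    Parameters absent from a model contribute a point mass at zero with
    that model's probability, so averaged means shrink toward zero for
    parameters few models carry.
    """
    names = []
    for fit in fits:
        for nm in fit.names:
            if nm not in names:
                names.append(nm)
    P = len(names)
    mean = np.zeros(P)
    second = np.zeros(P)
    for fit, pm in zip(fits, bms_result.probability):
        idx = {nm: i for i, nm in enumerate(fit.names)}
        var = np.diag(fit.cov)
        for j, nm in enumerate(names):
            if nm in idx:
                mu = fit.mean[idx[nm]]
                mean[j] += pm * mu
                second[j] += pm * (var[idx[nm]] + mu**2)
            # absent: adds 0 to both moments
    variance = np.maximum(second - mean**2, 0.0)
    return BMAResult(names, mean, variance)


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


def pearson(x, y):
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    import scipy.stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    r_squared: float
    weights: np.ndarray = None
    slope_ci: tuple = None
    n_redrawn: int = 0


def robust_regression(x, y, max_iter: int = 50, tol: float = 1e-8) -> RegressionResult:
    """IRLS robust line fit with Tukey bisquare weights (c = 4.685,
    scale = MAD/0.6745), plus F and R^2 on the weighted fit."""
    import warnings

    import scipy.stats
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=max_iter, tol=tol, scale_est="mad")
    if res.fit_history.get("iteration", 0) >= max_iter:
        warnings.warn("robust regression did not converge; returning last iterate")
    w = np.asarray(res.weights)
    # weighted R^2 / F on the converged weights
    sw = w.sum()
    ybar = (w * y).sum() / sw
    yhat = res.fittedvalues
    ss_res = float((w * (y - yhat) ** 2).sum())
    ss_tot = float((w * (y - ybar) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df1, df2 = 1, x.size - 2
    f_stat = (r2 / df1) / ((1.0 - r2) / df2) if r2 < 1 else np.inf
    p = float(scipy.stats.f.sf(f_stat, df1, df2))
    return RegressionResult(
        float(res.params[1]), float(res.params[0]), float(f_stat), p, float(r2), w
    )


def bootstrap_regression(
    x, y, n_boot: int = 1000, seed: int = 0, ci_level: float = 0.95
) -> RegressionResult:
    """Seeded case-resampling bootstrap around the robust line fit.

    Point estimates (slope/intercept/F/R^2) come from the full-sample
    robust fit; the slope confidence interval is the percentile interval
    over bootstrap resamples.  Degenerate resamples (zero x-variance) are
    redrawn and counted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations for the bootstrap")
    full = robust_regression(x, y)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if np.std(x[idx]) > 0:
                break
            redrawn += 1
        slopes[b] = robust_regression(x[idx], y[idx]).slope
    lo, hi = np.percentile(slopes, [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100])
    return RegressionResult(
        full.slope,
        full.intercept,
        full.f_statistic,
        full.p_value,
        full.r_squared,
        full.weights,
        (float(lo), float(hi)),
        redrawn,
    )
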