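"""Bayesian inversion of DCMs by variational Laplace.

A fixed-form Gaussian posterior over the model parameters is optimized by
Gauss-Newton ascent on the variational free energy

    F = accuracy - complexity,
    complexity = KL( q(theta) || p(theta) ),

with Gaussian observation noise whose log-precision (one per channel group,
e.g. per wavelength) is estimated under a weak Gaussian hyperprior.
Jacobians come from central finite differences; a Levenberg-style damping
schedule only ever accepts steps that increase F, so the accepted-step
trace is non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import integrate_epoch_average
from .generative import DCMSpec, HemodynamicParameters, FNIRSObservationModel

__all__ = [
    "PriorSpec",
    "ParameterPacking",
    "PosteriorFit",
    "pack_parameters",
    "variational_laplace",
    "free_energy_components",
    "make_session_generative",
    "fit_dcm",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorSpec:
    """Prior moments per parameter class (established DCM-style defaults).

    A off-diagonal couplings: N(0, n/64) Hz; self-connections are
    log-scalings of a -0.5 1/s decay with N(0, 1/256); modulatory B and
    driving C: N(0, 1); haemodynamic transit/stiffness log-scalings:
    N(0, 1/64); the optics scaling k has the informed log-normal prior
    log k ~ N(0, 1/16).  Noise log-precisions get N(hyper_mean, hyper_var).
    """

    a_offdiag_var: float = None  # default n/64, filled at packing time
    a_self_var: float = 1.0 / 256.0
    b_var: float = 1.0
    c_var: float = 1.0
    hemo_var: float = 1.0 / 64.0
    log_k_var: float = 1.0 / 16.0
    hyper_mean: float = 4.0
    hyper_var: float = 1.0

    def __post_init__(self):
        for name in ("a_self_var", "b_var", "c_var", "hemo_var", "log_k_var", "hyper_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ParameterPacking:
    """Deterministic flat ordering of a model's free parameters.

    Order: A off-diagonals (row-major over the mask), A diagonal
    log-scalings, B per input, C, haemodynamic log-scalings
    (transit then stiffness per region), observation parameters.
    """

    spec: DCMSpec
    names: list
    prior_mean: np.ndarray
    prior_var: np.ndarray
    mode: str  # "fnirs" or "bold"
    _blocks: dict = field(repr=False, default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def unpack_batch(self, Theta: np.ndarray, hemo: HemodynamicParameters):
        """Expand (K, p) parameter draws into kernel-ready arrays."""
        Theta = np.atleast_2d(np.asarray(Theta, dtype=float))
        K = Theta.shape[0]
        spec = self.spec
        n, m = spec.n_regions, spec.n_inputs
        A = np.tile(spec.A, (K, 1, 1))
        B = np.tile(spec.B, (K, 1, 1, 1))
        C = np.tile(spec.C, (K, 1, 1))
        bl = self._blocks
        offs = bl["a_off"]
        for slot, (i, j) in enumerate(offs["ij"]):
            A[:, i, j] = Theta[:, offs["start"] + slot]
        ds = bl["a_self"]
        for slot in range(n):
            A[:, slot, slot] = -0.5 * np.exp(Theta[:, ds["start"] + slot])
        bb = bl["b"]
        for slot, (k, i, j) in enumerate(bb["kij"]):
            B[:, k, i, j] = Theta[:, bb["start"] + slot]
        cc = bl["c"]
        for slot, (i, k) in enumerate(cc["ik"]):
            C[:, i, k] = Theta[:, cc["start"] + slot]
        hh = bl["hemo"]
        ks, ga, tau0, al0, E0 = hemo.per_region(n)
        tau = tau0[None] * np.exp(Theta[:, hh["start"] : hh["start"] + n])
        alpha = al0[None] * np.exp(Theta[:, hh["start"] + n : hh["start"] + 2 * n])
        alpha = np.clip(alpha, 1e-3, 0.95)
        out = {
            "A": A,
            "B": B,
            "C": C,
            "kappa_s": np.tile(ks, (K, 1)),
            "gamma": np.tile(ga, (K, 1)),
            "tau": tau,
            "alpha": alpha,
            "E0": np.tile(E0, (K, 1)),
        }
        if self.mode == "fnirs":
            out["k"] = np.exp(Theta[:, bl["obs"]["start"]])
        return out

    def pack(self, A=None, B=None, C=None, hemo_scalings=None, log_k=None) -> np.ndarray:
        """Inverse of unpacking for true parameter values (round-trip aid)."""
        theta = self.prior_mean.copy()
        bl = self._blocks
        if A is not None:
            A = np.asarray(A, float)
            for slot, (i, j) in enumerate(bl["a_off"]["ij"]):
                theta[bl["a_off"]["start"] + slot] = A[i, j]
            for slot in range(self.spec.n_regions):
                theta[bl["a_self"]["start"] + slot] = np.log(A[slot, slot] / -0.5)
        if B is not None:
            B = np.asarray(B, float)
            for slot, (k, i, j) in enumerate(bl["b"]["kij"]):
                theta[bl["b"]["start"] + slot] = B[k, i, j]
        if C is not None:
            C = np.asarray(C, float)
            for slot, (i, k) in enumerate(bl["c"]["ik"]):
                theta[bl["c"]["start"] + slot] = C[i, k]
        if hemo_scalings is not None:
            n = self.spec.n_regions
            theta[bl["hemo"]["start"] : bl["hemo"]["start"] + 2 * n] = hemo_scalings
        if log_k is not None and self.mode == "fnirs":
            theta[bl["obs"]["start"]] = log_k
        return theta


def pack_parameters(spec: DCMSpec, priors: PriorSpec = None, mode: str = "fnirs") -> ParameterPacking:
    """Build the flat parameter vector layout and matching priors."""
    if priors is None:
        priors = PriorSpec()
    n, m = spec.n_regions, spec.n_inputs
    a_off_var = priors.a_offdiag_var if priors.a_offdiag_var is not None else n / 64.0

    names, mean, var = [], [], []
    blocks = {}

    ij = [(i, j) for i in range(n) for j in range(n) if i != j and spec.A_mask[i, j]]
    blocks["a_off"] = {"start": 0, "ij": ij}
    for i, j in ij:
        names.append(f"A:{spec.regions[j]}->{spec.regions[i]}")
        mean.append(0.0)
        var.append(a_off_var)

    blocks["a_self"] = {"start": len(names)}
    for i in range(n):
        names.append(f"A_self:{spec.regions[i]}")
        mean.append(0.0)
        var.append(priors.a_self_var)

    kij = [
        (k, i, j)
        for k in range(m)
        for i in range(n)
        for j in range(n)
        if spec.B_mask[k, i, j]
    ]
    blocks["b"] = {"start": len(names), "kij": kij}
    for k, i, j in kij:
        names.append(f"B:{spec.inputs[k]}:{spec.regions[j]}->{spec.regions[i]}")
        mean.append(0.0)
        var.append(priors.b_var)

    ik = [(i, k) for i in range(n) for k in range(m) if spec.C_mask[i, k]]
    blocks["c"] = {"start": len(names), "ik": ik}
    for i, k in ik:
        names.append(f"C:{spec.inputs[k]}->{spec.regions[i]}")
        mean.append(0.0)
        var.append(priors.c_var)

    blocks["hemo"] = {"start": len(names)}
    for label in ("tau", "alpha"):
        for i in range(n):
            names.append(f"hemo_{label}:{spec.regions[i]}")
            mean.append(0.0)
            var.append(priors.hemo_var)

    if mode == "fnirs":
        blocks["obs"] = {"start": len(names)}
        names.append("obs_log_k")
        mean.append(0.0)
        var.append(priors.log_k_var)
    elif mode != "bold":
        raise ValueError(f"unknown observation mode {mode!r}")

    return ParameterPacking(
        spec, names, np.array(mean), np.array(var), mode, blocks
    )


# ---------------------------------------------------------------------------
# Variational Laplace
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """Posterior moments, noise hyperparameters and free energy."""

    mean: np.ndarray
    cov: np.ndarray
    log_precisions: np.ndarray  # per noise group
    free_energy: float
    trace: list
    prediction: np.ndarray
    accuracy: float
    complexity: float
    names: list = None
    prior_mean: np.ndarray = None
    prior_cov: np.ndarray = None

    def credible_interval(self, level: float = 0.9) -> np.ndarray:
        """Central credible intervals per parameter, (p, 2)."""
        from scipy.stats import norm

        zc = norm.ppf(0.5 + level / 2.0)
        sd = np.sqrt(np.diag(self.cov))
        return np.column_stack([self.mean - zc * sd, self.mean + zc * sd])

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "names": self.names,
                "mean": self.mean.tolist(),
                "cov": self.cov.tolist(),
                "log_precisions": np.asarray(self.log_precisions).tolist(),
                "free_energy": self.free_energy,
                "accuracy": self.accuracy,
                "complexity": self.complexity,
                "trace": [float(f) for f in self.trace],
            },
            indent=2,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def free_energy_components(fit: PosteriorFit):
    """Return (accuracy, complexity) with F = accuracy - complexity."""
    return fit.accuracy, fit.complexity


def _kl_gaussian(m, S, m0, S0):
    p = len(m)
    S0_inv = np.linalg.inv(S0)
    d = m - m0
    _, ld0 = np.linalg.slogdet(S0)
    _, ld = np.linalg.slogdet(S)
    return 0.5 * (np.trace(S0_inv @ S) + d @ S0_inv @ d - p + ld0 - ld)


def variational_laplace(
    generative,
    prior_mean,
    prior_cov,
    data,
    noise_groups=None,
    *,
    hyper_mean: float = 4.0,
    hyper_var: float = 1.0,
    fixed_noise_precision=None,
    max_iter: int = 64,
    tol: float = 0.01,
    fd_step: float = 1e-4,
    fd_scheme: str = "central",
    vectorized: bool = False,
    names=None,
) -> PosteriorFit:
    """Gauss-Newton variational Laplace under Gaussian priors and noise.

    Parameters
    ----------
    generative : callable mapping a parameter vector (p,) to a prediction
        (N,); with ``vectorized=True`` it maps (K, p) to (K, N) (used to
        batch finite-difference Jacobians).  May return NaN/inf rows to
        signal an unstable parameter set.
    prior_cov : full covariance matrix or a variance vector.
    noise_groups : list of index arrays partitioning the data vector; one
        noise log-precision is estimated per group (default: one group).
    fixed_noise_precision : scalar or per-group array; when given, the
        noise precisions are held fixed and no hyperprior penalty enters F
        (the conjugate linear-Gaussian case then reproduces the closed-form
        model evidence).
    """
    y = np.asarray(data, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("data contains non-finite values")
    m0 = np.asarray(prior_mean, dtype=float).copy()
    p = m0.size
    S0 = np.asarray(prior_cov, dtype=float)
    if S0.ndim == 1:
        S0 = np.diag(S0)
    S0_inv = np.linalg.inv(S0)
    N = y.size
    if noise_groups is None:
        noise_groups = [np.arange(N)]
    noise_groups = [np.asarray(g, dtype=int) for g in noise_groups]
    G = len(noise_groups)

    def eval_batch(Theta):
        Theta = np.atleast_2d(Theta)
        if vectorized:
            return np.atleast_2d(generative(Theta))
        return np.stack([np.asarray(generative(t), dtype=float).ravel() for t in Theta])

    def jacobian(m):
        h = fd_step * (1.0 + np.abs(m))
        if fd_scheme == "central":
            Theta = np.concatenate([[m], m + np.diag(h), m - np.diag(h)])
        else:  # forward differences: half the model evaluations
            Theta = np.concatenate([[m], m + np.diag(h)])
        preds = eval_batch(Theta)
        if not np.all(np.isfinite(preds[0])):
            raise FloatingPointError("generative model non-finite at expansion point")
        if fd_scheme == "central":
            J = (preds[1 : 1 + p] - preds[1 + p :]).T / (2.0 * h)[None, :]
            bad = ~np.all(np.isfinite(J), axis=0)
            if np.any(bad):
                # one-sided fallback for parameters whose perturbation failed
                J[:, bad] = ((preds[1 : 1 + p][bad] - preds[0]) / h[bad, None]).T
        else:
            J = (preds[1 : 1 + p] - preds[0]).T / h[None, :]
        if not np.all(np.isfinite(J)):
            raise FloatingPointError("Jacobian non-finite")
        return preds[0], J

    fixed = fixed_noise_precision is not None
    if fixed:
        lam = np.log(np.broadcast_to(np.asarray(fixed_noise_precision, float), (G,))).copy()
    else:
        lam = np.full(G, float(hyper_mean))

    def update_lambda(r, J, S, lam):
        if fixed:
            return lam
        lam = lam.copy()
        JS = J @ S  # (N, p)
        for gi, g in enumerate(noise_groups):
            E = float(r[g] @ r[g] + np.einsum("ij,ij->", JS[g], J[g]))
            Ng = len(g)
            x = lam[gi]
            for _ in range(8):  # 1-D Newton on F(lambda_g)
                grad = -0.5 * np.exp(x) * E + 0.5 * Ng - (x - hyper_mean) / hyper_var
                curv = -0.5 * np.exp(x) * E - 1.0 / hyper_var
                step = grad / curv
                x -= step
                if abs(step) < 1e-9:
                    break
            lam[gi] = x
        return lam

    def posterior_cov(J, lam):
        H = S0_inv.copy()
        for gi, g in enumerate(noise_groups):
            H = H + np.exp(lam[gi]) * (J[g].T @ J[g])
        H = 0.5 * (H + H.T)
        S = np.linalg.inv(H)
        return 0.5 * (S + S.T), H

    def free_energy(m, r, J, S, lam):
        acc = 0.0
        JS = J @ S
        for gi, g in enumerate(noise_groups):
            Ng = len(g)
            E = float(r[g] @ r[g] + np.einsum("ij,ij->", JS[g], J[g]))
            acc += -0.5 * Ng * LOG2PI + 0.5 * Ng * lam[gi] - 0.5 * np.exp(lam[gi]) * E
        if not fixed:
            acc += -0.5 * np.sum((lam - hyper_mean) ** 2) / hyper_var
        comp = _kl_gaussian(m, S, m0, S0)
        return acc - comp, acc, comp

    # initial state at the prior mean
    m = m0.copy()
    g0, J = jacobian(m)
    r = y - g0
    lam = update_lambda(r, J, np.zeros((p, p)), lam)
    S, H = posterior_cov(J, lam)
    lam = update_lambda(r, J, S, lam)
    S, H = posterior_cov(J, lam)
    F, acc, comp = free_energy(m, r, J, S, lam)
    trace = [F]
    pred = g0

    damping = 1e-4
    for _ in range(max_iter):
        grad = -S0_inv @ (m - m0)
        Hgn = S0_inv.copy()
        for gi, g in enumerate(noise_groups):
            pi = np.exp(lam[gi])
            grad = grad + pi * (J[g].T @ r[g])
            Hgn = Hgn + pi * (J[g].T @ J[g])
        accepted = False
        for _retry in range(16):
            M = Hgn + damping * np.diag(np.diag(Hgn))
            try:
                step = np.linalg.solve(M, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(M, grad, rcond=None)[0]
            m_new = m + step
            try:
                g_new, J_new = jacobian(m_new)
            except FloatingPointError:
                damping *= 10.0
                continue
            r_new = y - g_new
            S_try, _ = posterior_cov(J_new, lam)
            lam_new = update_lambda(r_new, J_new, S_try, lam)
            S_new, _ = posterior_cov(J_new, lam_new)
            F_new, acc_new, comp_new = free_energy(m_new, r_new, J_new, S_new, lam_new)
            if np.isfinite(F_new) and F_new > F:
                dF = F_new - F
                m, r, J, S, lam = m_new, r_new, J_new, S_new, lam_new
                F, acc, comp = F_new, acc_new, comp_new
                pred = g_new
                trace.append(F)
                damping = max(damping * 0.5, 1e-8)
                accepted = True
                break
            damping *= 4.0
        if not accepted or dF < tol:
            break

    if not np.isfinite(F):
        raise RuntimeError(f"non-finite free energy; parameter snapshot: {m}")
    # guard: symmetrize and floor tiny negative eigenvalues
    w, V = np.linalg.eigh(S)
    if w.min() < -1e-10:
        w = np.clip(w, 1e-12, None)
        S = V @ np.diag(w) @ V.T
    return PosteriorFit(
        m, S, lam, float(F), trace, pred, float(acc), float(comp), names, m0, S0
    )


# ---------------------------------------------------------------------------
# DCM-specific generative wrappers
# ---------------------------------------------------------------------------


def _whitening_weights(avg) -> np.ndarray:
    """Zero-phase spectral weights 1/sqrt(noise periodogram), shape
    (n_out, ncond, n_freq).

    The noise spectrum of the trial average is estimated from the
    per-epoch residuals about each condition mean (average periodogram over
    n epochs, scaled by 1/(n-1): n-1 degrees of freedom per bin), smoothed
    over neighbouring frequency bins, and floored at a fraction of its
    median so estimation noise cannot produce wild weights.
    """
    window = avg.window_samples
    Ps = []
    for ci, cond in enumerate(avg.conditions):
        R = avg.epoch_residuals[cond]  # (n_epochs, n_out, window)
        nE = R.shape[0]
        P = (np.abs(np.fft.rfft(R, axis=-1)) ** 2).mean(axis=0) / max(nE - 1, 1)
        Ps.append(P)
    P = np.stack(Ps, axis=1)  # (n_out, ncond, nf)
    k = 5  # moving-average smoothing over frequency
    pad = np.pad(P, ((0, 0), (0, 0), (k // 2, k // 2)), mode="edge")
    Psm = np.stack([pad[:, :, i : i + P.shape[-1]] for i in range(k)]).mean(axis=0)
    floor = 0.1 * np.median(Psm, axis=-1, keepdims=True) + 1e-300
    W = 1.0 / np.sqrt(np.maximum(Psm, floor))
    # normalize so the mean squared weight is 1 (scale handled downstream)
    return W / np.sqrt((W**2).mean(axis=-1, keepdims=True))


def make_session_generative(
    packing: ParameterPacking,
    hemo: HemodynamicParameters,
    session_inputs: np.ndarray,
    epoch_starts: dict,
    conditions,
    window: int,
    n_pre: int,
    obs_model: FNIRSObservationModel = None,
    bold_model=None,
    dt: float = 0.1,
):
    """Vectorized generative model predicting trial-averaged responses by
    integrating the full session and averaging the same epochs as the data.

    ``session_inputs`` is the (n_inputs, T) stimulus matrix on the output
    grid; ``epoch_starts`` maps each condition to the window start samples
    actually used when the data were trial-averaged, so model prediction
    and data pass through the identical linear averaging/baselining
    operator.  Returns a callable (K, p) -> (K, N) for
    ``variational_laplace(vectorized=True)``.
    """
    from .generative import BOLDObservationModel

    U = np.asarray(session_inputs, dtype=float)
    mode = packing.mode
    if mode == "fnirs" and obs_model is None:
        raise ValueError("fnirs mode requires an observation model")
    if bold_model is None:
        bold_model = BOLDObservationModel(E0=float(np.atleast_1d(hemo.E0)[0]))
    starts, conds = [], []
    for ci, cond in enumerate(conditions):
        for a in epoch_starts[cond]:
            starts.append(a)
            conds.append(ci)
    starts = np.asarray(starts, dtype=np.int64)
    conds = np.asarray(conds, dtype=np.int64)
    ncond = len(conditions)
    bold_consts = np.array(
        [bold_model.V0, bold_model.k1, bold_model.k2, bold_model.k3]
    )
    if mode == "fnirs":
        GH, GQ = obs_model.gain_matrices(k=1.0)
        # y = GH*dHc + GQ*dQc with dHc = HbT0(v-1) - HbR0(q-1), dQc = HbR0(q-1)
        Mv = hemo.HbT0 * GH  # (nw, nch, n)
        Mq = hemo.HbR0 * (GQ - GH)

    def generative(Theta):
        Theta = np.atleast_2d(Theta)
        K = Theta.shape[0]
        parts = packing.unpack_batch(Theta, hemo)
        v, q, b, counts, bad = integrate_epoch_average(
            parts["A"],
            parts["B"],
            parts["C"],
            parts["kappa_s"],
            parts["gamma"],
            parts["tau"],
            parts["alpha"],
            parts["E0"],
            U,
            float(dt),
            starts,
            conds,
            ncond,
            int(window),
            bold_consts,
        )
        if mode == "fnirs":
            y = np.einsum("wcr,kdrt->kwcdt", Mv, v - 1.0) + np.einsum(
                "wcr,kdrt->kwcdt", Mq, q - 1.0
            )
            # rows (wavelength x channel), columns (condition x window)
            y = y.reshape(K, -1, ncond, window) * parts["k"][:, None, None, None]
        else:
            y = np.transpose(b, (0, 2, 1, 3))  # (K, n, ncond, window)
        y = y - y[..., :n_pre].mean(axis=-1, keepdims=True)
        y = y.reshape(K, y.shape[1], -1)
        y = np.where(bad[:, None, None].astype(bool), np.nan, y)
        return y.reshape(K, -1)

    return generative


def fit_dcm(
    avg,
    packing: ParameterPacking,
    hemo: HemodynamicParameters,
    session_inputs: np.ndarray,
    obs_model: FNIRSObservationModel = None,
    priors: PriorSpec = None,
    dt: float = 0.1,
    max_iter: int = 64,
    tol: float = 0.01,
    fd_scheme: str = "central",
    whiten: bool = True,
) -> PosteriorFit:
    """Fit one DCM to trial-averaged data.

    ``avg`` is an :class:`babydcm.preprocess.EpochAverage`; the generative
    model integrates the same session design and applies the identical
    epoch-averaging operator.  Data and predictions are jointly rescaled to
    unit data SD before inversion (a common scale for all models of one
    dataset), which places the noise log-precision in the range of its weak
    hyperprior without changing the parameter posterior.

    With ``whiten`` (default), residual noise in the trial average is
    spectrally flattened before inversion: the split-half (odd-even epoch)
    difference carried by ``avg`` gives a model-free periodogram of the
    averaging noise per channel and condition, and a zero-phase weighting
    1/sqrt(spectrum) is applied identically to data and predictions.  This
    is generalized least squares against the residual physiological noise
    (Mayer/cardiac bands surviving trial averaging, motion residues) and
    leaves the likelihood well calibrated where a white-noise assumption
    would be overconfident; the weighting is data-derived, hence shared by
    every model compared on the same dataset.
    """
    if priors is None:
        priors = PriorSpec()
    data = np.atleast_2d(np.asarray(avg.data, dtype=float))
    n_out, T = data.shape
    window = avg.window_samples
    ncond = len(avg.conditions)
    n_pre = max(1, int(round(-avg.window_s[0] * avg.sampling_rate)))
    gen = make_session_generative(
        packing,
        hemo,
        session_inputs,
        avg.epoch_starts,
        avg.conditions,
        window,
        n_pre,
        obs_model=obs_model,
        dt=dt,
    )

    if whiten and avg.epoch_residuals is not None:
        W = _whitening_weights(avg)  # (n_out, ncond, nf)

        def project(Y):
            shp = Y.shape
            Z = Y.reshape(shp[:-1] + (ncond, window))
            F = np.fft.rfft(Z, axis=-1)
            return np.fft.irfft(F * W, n=window, axis=-1).reshape(shp)

    else:

        def project(Y):
            return Y

    data = project(data)
    scale = 1.0 / max(data.std(), 1e-12)

    def gen_scaled(Theta):
        K = np.atleast_2d(Theta).shape[0]
        Y = gen(Theta).reshape(K, n_out, T)
        return (project(Y) * scale).reshape(K, -1)

    # one noise log-precision per output row (channel-wavelength for fNIRS,
    # region for BOLD): a motion-damaged channel is then down-weighted
    # instead of polluting a shared precision
    groups = [np.arange(T) + r * T for r in range(n_out)]

    return variational_laplace(
        gen_scaled,
        packing.prior_mean,
        np.diag(packing.prior_var),
        (data * scale).ravel(),
        noise_groups=groups,
        hyper_mean=priors.hyper_mean,
        hyper_var=priors.hyper_var,
        max_iter=max_iter,
        tol=tol,
        vectorized=True,
        names=packing.names,
        fd_scheme=fd_scheme,
    )
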