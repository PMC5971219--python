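"""Block design construction, HRF-convolved design matrices, GLM fitting
and regional eigenvariate extraction.

The study design is 24 auditory blocks (12 "voice" V, 12 "non-voice" NV) of
9 s separated by at least 13 s of rest in an 11.5-minute session sampled at
10 Hz.  Evoked responses are modelled as onsets convolved with a canonical
double-gamma haemodynamic response plus its temporal and dispersion
derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.special

__all__ = [
    "BlockEvent",
    "BlockDesign",
    "DesignMatrix",
    "build_block_design",
    "canonical_hrf_basis",
    "build_design_matrix",
    "fit_glm",
    "extract_eigenvariate",
]

CONDITIONS = ("V", "NV")


@dataclass(frozen=True)
class BlockEvent:
    condition: str
    onset: float  # s
    duration: float  # s


@dataclass
class BlockDesign:
    """Ordered stimulus events plus session geometry."""

    events: list
    session_length: float
    sampling_rate: float = 10.0
    min_rest: float = 13.0

    def __post_init__(self):
        onsets = [ev.onset for ev in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for ev in self.events:
            if ev.onset + ev.duration > self.session_length + 1e-9:
                raise ValueError(f"event at {ev.onset}s extends past the session end")
        for prev, nxt in zip(self.events, self.events[1:]):
            gap = nxt.onset - (prev.onset + prev.duration)
            if gap < self.min_rest - 1e-9:
                raise ValueError(f"inter-block gap {gap:.2f}s below the minimum rest")

    @property
    def conditions(self):
        seen = []
        for ev in self.events:
            if ev.condition not in seen:
                seen.append(ev.condition)
        return sorted(
            seen,
            key=lambda c: (CONDITIONS.index(c), "") if c in CONDITIONS else (len(CONDITIONS), c),
        )

    @property
    def n_samples(self) -> int:
        return int(round(self.session_length * self.sampling_rate))

    def input_functions(self, sampling_rate=None, n_samples=None) -> np.ndarray:
        """Boxcar stimulus functions, one row per condition (V, NV order)."""
        fs = sampling_rate or self.sampling_rate
        T = n_samples or int(round(self.session_length * fs))
        conds = self.conditions
        U = np.zeros((len(conds), T))
        for ev in self.events:
            r = conds.index(ev.condition)
            a = int(round(ev.onset * fs))
            b = min(T, int(round((ev.onset + ev.duration) * fs)))
            U[r, a:b] = 1.0
        return U

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(ev.condition, ev.onset, ev.duration) for ev in self.events],
            columns=["condition", "onset", "duration"],
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame, session_length, sampling_rate=10.0, min_rest=13.0):
        events = [
            BlockEvent(str(r.condition), float(r.onset), float(r.duration))
            for r in frame.itertuples()
        ]
        return cls(events, session_length, sampling_rate, min_rest)


def build_block_design(
    n_per_condition: int = 12,
    duration: float = 9.0,
    min_rest: float = 13.0,
    session: float = 690.0,
    seed: int = 0,
    sampling_rate: float = 10.0,
    start: float = 30.0,
    max_jitter: float = 4.0,
) -> BlockDesign:
    """Seeded shuffled block design with jittered rest periods (>= min_rest).

    The default start offset leaves enough lead-in for trial averaging with
    input history; jitter decorrelates slow physiological oscillations from
    the block structure.
    """
    rng = np.random.default_rng(seed)
    n_blocks = 2 * n_per_condition
    required = start + n_blocks * duration + (n_blocks - 1) * min_rest + duration
    if required > session:
        raise ValueError(
            f"cannot pack {n_blocks} blocks into {session}s; needs >= {required:.0f}s"
        )
    order = np.array([CONDITIONS[0]] * n_per_condition + [CONDITIONS[1]] * n_per_condition)
    rng.shuffle(order)
    # shrink jitter if the nominal packing would overflow the session
    slack = session - required
    jit_max = min(max_jitter, slack / max(1, n_blocks - 1)) if n_blocks > 1 else 0.0
    events, t = [], float(start)
    for cond in order:
        events.append(BlockEvent(str(cond), round(t, 1), duration))
        t += duration + min_rest + rng.uniform(0, jit_max)
    return BlockDesign(events, session, sampling_rate, min_rest)


# ---------------------------------------------------------------------------
# HRF basis
# ---------------------------------------------------------------------------


def _double_gamma(t, peak=6.0, undershoot=16.0, ratio=6.0, disp=1.0):
    """Canonical double-gamma HRF (response peak ~6 s, undershoot ~16 s)."""
    t = np.asarray(t, dtype=float)
    a1, a2 = peak / disp, undershoot / disp
    h = (t / disp) ** (a1) * np.exp(-t / disp) / scipy.special.gamma(a1 + 1) - (
        (t / disp) ** (a2) * np.exp(-t / disp) / scipy.special.gamma(a2 + 1)
    ) / ratio
    h[t < 0] = 0.0
    return h


def canonical_hrf_basis(sampling_rate: float, length_s: float = 32.0):
    """Canonical HRF, temporal derivative (1 s shift finite difference) and
    dispersion derivative (finite difference w.r.t. peak dispersion).

    Returns (basis (3, L) array, names).
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    t = np.arange(0.0, length_s, 1.0 / sampling_rate)
    h = _double_gamma(t)
    h_shift = _double_gamma(t - 1.0)
    d_temporal = h - h_shift
    dd = 0.01
    d_dispersion = (h - _double_gamma(t, disp=1.0 + dd)) / dd
    basis = np.stack([h, d_temporal, d_dispersion])
    return basis, ["canonical", "temporal_derivative", "dispersion_derivative"]


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # samples x regressors
    names: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError(f"design matrix rank-deficient; columns: {self.names}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=self.names)


def build_design_matrix(
    design: BlockDesign, basis=None, boxcar: bool = False
) -> DesignMatrix:
    """Convolve condition onsets with each basis function.

    ``boxcar=True`` encodes each block as a sustained epoch rather than a
    delta at onset.  Columns are mean-centred except the constant.
    """
    fs = design.sampling_rate
    T = design.n_samples
    if basis is None:
        basis, basis_names = canonical_hrf_basis(fs)
    else:
        basis, basis_names = basis
    cols, names = [], []
    for cond in design.conditions:
        stick = np.zeros(T)
        for ev in design.events:
            if ev.condition != cond:
                continue
            a = int(round(ev.onset * fs))
            if boxcar:
                b = min(T, int(round((ev.onset + ev.duration) * fs)))
                stick[a:b] = 1.0
            else:
                stick[a] = 1.0
        for b_row, b_name in zip(basis, basis_names):
            col = np.convolve(stick, b_row)[:T]
            cols.append(col - col.mean())
            names.append(f"{cond}:{b_name}")
    cols.append(np.ones(T))
    names.append("constant")
    return DesignMatrix(np.column_stack(cols), names)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


@dataclass
class GLMFit:
    beta: np.ndarray
    residual_variance: float
    names: list
    xtx_inv: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def t_statistic(self, contrast) -> float:
        c = np.asarray(contrast, dtype=float)
        num = c @ self.beta
        den = np.sqrt(self.residual_variance * c @ self.xtx_inv @ c)
        return float(num / den)


def fit_glm(y: np.ndarray, X: DesignMatrix) -> GLMFit:
    """Ordinary least squares with t-statistics per contrast."""
    y = np.asarray(y, dtype=float).ravel()
    M = X.matrix
    if M.shape[0] != y.shape[0]:
        raise ValueError("sample count mismatch between data and design")
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1]:
        raise ValueError("design matrix is rank deficient")
    r = y - M @ beta
    dof = M.shape[0] - M.shape[1]
    sigma2 = float(r @ r / dof)
    xtx_inv = np.linalg.inv(M.T @ M)
    return GLMFit(beta, sigma2, list(X.names), xtx_inv, r)


def extract_eigenvariate(signals: np.ndarray, positions=None, centre=None, radius: float = 4.0):
    """First principal eigenvariate of the signals within a sphere.

    ``signals`` is channels/voxels x samples.  When ``positions`` and
    ``centre`` are given, rows are restricted to those within ``radius`` mm
    of the centre first.  The eigenvariate is the first left singular vector
    of the mean-centred matrix, scaled by singular value / sqrt(n), with the
    sign fixed so the loading sum is positive.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if positions is not None:
        positions = np.asarray(positions, dtype=float)
        d = np.linalg.norm(positions - np.asarray(centre, dtype=float), axis=1)
        keep = d <= radius
        if not np.any(keep):
            raise ValueError(f"no signals within {radius} mm of {centre}")
        signals = signals[keep]
    if signals.shape[0] == 0:
        raise ValueError("empty signal set")
    Xc = signals - signals.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    v = U[:, 0] * s[0] / np.sqrt(signals.shape[0])
    if Vt[0].sum() < 0:
        v = -v
    return v
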