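"""The forward (generative) model: bilinear neural dynamics, balloon
haemodynamics, and the observation equations for fNIRS optical density and
BOLD.

Neural states z (one per region) follow the bilinear state equation

    dz/dt = (A + sum_j u_j B_j) z + C u

with intrinsic coupling A (Hz), input-dependent modulation B and driving
inputs C.  Each region's neural activity drives a balloon model (vasoactive
signal s, inflow f, venous volume v, deoxyhaemoglobin q).  Volume and
deoxyhaemoglobin map to cortical chromophore changes (dHc oxy-, dQc
deoxy-Hb, uM), which project to channel optical-density measurements through
wavelength-specific extinction coefficients, pial-vein correction factors,
and the optical sensitivity matrix S = k * S0, where S0 comes from photon
transport and k is a free scaling accommodating source strength and
detection efficiency.  A standard BOLD observation provides the fMRI twin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._kernels import integrate_batch

__all__ = [
    "DCMSpec",
    "HemodynamicParameters",
    "FNIRSObservationModel",
    "BOLDObservationModel",
    "neural_derivative",
    "hemodynamic_derivative",
    "chromophore_changes",
    "observe_fnirs",
    "observe_bold",
    "integrate_dcm",
    "integrate_states",
]

REGIONS = ("IFG", "STS", "TPJ")
INPUTS = ("V", "NV")


@dataclass
class DCMSpec:
    """One model: regions, intrinsic A, modulatory B per input, driving C.

    Structural zeros are exactly zero and stay zero; the boolean masks mark
    which entries are free parameters.
    """

    regions: tuple = REGIONS
    inputs: tuple = INPUTS
    A: np.ndarray = None
    B: np.ndarray = None  # (n_inputs, n, n)
    C: np.ndarray = None  # (n, n_inputs)
    A_mask: np.ndarray = None
    B_mask: np.ndarray = None
    C_mask: np.ndarray = None
    name: str = "model"

    def __post_init__(self):
        n, m = len(self.regions), len(self.inputs)
        if self.A is None:
            self.A = -0.5 * np.eye(n)
        if self.B is None:
            self.B = np.zeros((m, n, n))
        if self.C is None:
            self.C = np.zeros((n, m))
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.A.shape != (n, n) or self.B.shape != (m, n, n) or self.C.shape != (n, m):
            raise ValueError("A/B/C dimensions inconsistent with regions/inputs")
        if self.A_mask is None:
            self.A_mask = self.A != 0
            np.fill_diagonal(self.A_mask, True)
        if self.B_mask is None:
            self.B_mask = self.B != 0
        if self.C_mask is None:
            self.C_mask = self.C != 0
        self.A_mask = np.asarray(self.A_mask, dtype=bool)
        self.B_mask = np.asarray(self.B_mask, dtype=bool)
        self.C_mask = np.asarray(self.C_mask, dtype=bool)
        if np.any(self.A[~self.A_mask] != 0):
            raise ValueError("structural zeros of A must be exactly zero")
        if np.any(self.B[~self.B_mask] != 0) or np.any(self.C[~self.C_mask] != 0):
            raise ValueError("structural zeros of B/C must be exactly zero")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    def region_index(self, name: str) -> int:
        return self.regions.index(name)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "regions": list(self.regions),
                "inputs": list(self.inputs),
                "A": self.A.tolist(),
                "B": self.B.tolist(),
                "C": self.C.tolist(),
                "A_mask": self.A_mask.astype(int).tolist(),
                "B_mask": self.B_mask.astype(int).tolist(),
                "C_mask": self.C_mask.astype(int).tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DCMSpec":
        d = json.loads(text)
        return cls(
            regions=tuple(d["regions"]),
            inputs=tuple(d["inputs"]),
            A=np.array(d["A"]),
            B=np.array(d["B"]),
            C=np.array(d["C"]),
            A_mask=np.array(d["A_mask"], dtype=bool),
            B_mask=np.array(d["B_mask"], dtype=bool),
            C_mask=np.array(d["C_mask"], dtype=bool),
            name=d.get("name", "model"),
        )


@dataclass
class HemodynamicParameters:
    """Balloon-model constants per region (broadcast scalars allowed).

    kappa_s: vasoactive signal decay (1/s); gamma: flow autoregulation
    (1/s); tau: venous transit time (s); alpha: vessel stiffness exponent
    (0 < alpha < 1); E0: resting oxygen extraction.  HbT0/HbR0 are baseline
    total/deoxy haemoglobin concentrations (uM) used by the chromophore
    mapping; only their products with the sensitivity scaling are
    identifiable from data.
    """

    kappa_s: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.32
    HbT0: float = 100.0
    HbR0: float = 40.0

    def __post_init__(self):
        for name in ("kappa_s", "gamma", "tau", "alpha", "E0", "HbT0", "HbR0"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if not np.all((0 < np.asarray(self.alpha)) & (np.asarray(self.alpha) < 1)):
            raise ValueError("alpha must lie in (0, 1)")

    def per_region(self, n: int):
        """Expand to per-region arrays (kappa_s, gamma, tau, alpha, E0)."""
        return tuple(
            np.broadcast_to(np.asarray(getattr(self, k), dtype=float), (n,)).copy()
            for k in ("kappa_s", "gamma", "tau", "alpha", "E0")
        )


@dataclass
class FNIRSObservationModel:
    """Augmented optics observation: y(lambda) = eps_H W_H S dHc + eps_Q W_Q S dQc
    per wavelength, with S = k * S0."""

    wavelengths: tuple
    eps_H: np.ndarray  # per wavelength, uM^-1 mm^-1
    eps_Q: np.ndarray
    S0: np.ndarray  # (n_wavelengths, n_channels, n_regions)
    W_H: np.ndarray = None
    W_Q: np.ndarray = None
    k: float = 1.0

    def __post_init__(self):
        self.eps_H = np.asarray(self.eps_H, dtype=float)
        self.eps_Q = np.asarray(self.eps_Q, dtype=float)
        self.S0 = np.asarray(self.S0, dtype=float)
        nw = len(self.wavelengths)
        if self.W_H is None:
            self.W_H = np.ones(nw)
        if self.W_Q is None:
            self.W_Q = np.ones(nw)
        self.W_H = np.asarray(self.W_H, dtype=float)
        self.W_Q = np.asarray(self.W_Q, dtype=float)
        if np.any(self.eps_H <= 0) or np.any(self.eps_Q <= 0):
            raise ValueError("extinction coefficients must be positive")
        if self.k <= 0:
            raise ValueError("sensitivity scaling k must be positive")
        if self.S0.shape[0] != nw:
            raise ValueError("S0 wavelength axis mismatch")

    @property
    def n_channels(self) -> int:
        return self.S0.shape[1]

    @property
    def n_regions(self) -> int:
        return self.S0.shape[2]

    def gain_matrices(self, k: float = None):
        """Per-wavelength (G_H, G_Q) channel x region gains with S = k*S0."""
        k = self.k if k is None else k
        if k <= 0:
            raise ValueError("sensitivity scaling k must be positive")
        S = k * self.S0
        GH = self.eps_H[:, None, None] * self.W_H[:, None, None] * S
        GQ = self.eps_Q[:, None, None] * self.W_Q[:, None, None] * S
        return GH, GQ


@dataclass
class BOLDObservationModel:
    """Classic BOLD signal model y = V0 (k1(1-q) + k2(1-q/v) + k3(1-v))."""

    V0: float = 0.04
    E0: float = 0.32

    @property
    def k1(self):
        return 7.0 * self.E0

    @property
    def k2(self):
        return 2.0

    @property
    def k3(self):
        return 2.0 * self.E0 - 0.2


# ---------------------------------------------------------------------------
# Single-evaluation derivatives (reference implementations; the integrator
# uses the compiled batch kernel)
# ---------------------------------------------------------------------------


def neural_derivative(z, u, spec: DCMSpec) -> np.ndarray:
    """dz/dt = (A + sum_j u_j B_j) z + C u."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    if z.shape != (spec.n_regions,) or u.shape != (spec.n_inputs,):
        raise ValueError("state/input dimension mismatch with the model spec")
    Aeff = spec.A + np.tensordot(u, spec.B, axes=1)
    return Aeff @ z + spec.C @ u


def hemodynamic_derivative(state, z, params: HemodynamicParameters):
    """Balloon-model derivatives for state (s, f, v, q) per region."""
    s, f, v, q = (np.asarray(x, dtype=float) for x in state)
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("f, v, q must remain positive")
    n = s.shape[0]
    ks, ga, tau, al, E0 = params.per_region(n)
    ds = np.asarray(z, dtype=float) - ks * s - ga * (f - 1.0)
    df = s
    fv = v ** (1.0 / al)
    dv = (f - fv) / tau
    ef = 1.0 - (1.0 - E0) ** (1.0 / f)
    dq = (f * ef / E0 - fv * q / v) / tau
    return ds, df, dv, dq


def chromophore_changes(v, q, params: HemodynamicParameters):
    """Map (v, q) to cortical chromophore changes in uM:
    dHbT = HbT0 (v-1); dQc = HbR0 (q-1); dHc = dHbT - dQc."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be positive")
    dHbT = params.HbT0 * (v - 1.0)
    dQc = params.HbR0 * (q - 1.0)
    dHc = dHbT - dQc
    return dHc, dQc


def observe_fnirs(dHc, dQc, model: FNIRSObservationModel) -> np.ndarray:
    """Optical-density measurements stacked over wavelengths:
    (n_wavelengths * n_channels, T)."""
    dHc = np.atleast_2d(np.asarray(dHc, dtype=float))
    dQc = np.atleast_2d(np.asarray(dQc, dtype=float))
    GH, GQ = model.gain_matrices()
    y = np.einsum("wcr,rt->wct", GH, dHc) + np.einsum("wcr,rt->wct", GQ, dQc)
    return y.reshape(-1, dHc.shape[1])


def observe_bold(v, q, model: BOLDObservationModel = None) -> np.ndarray:
    """BOLD signal per region from venous volume and deoxyhaemoglobin."""
    if model is None:
        model = BOLDObservationModel()
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    return model.V0 * (
        model.k1 * (1.0 - q) + model.k2 * (1.0 - q / v) + model.k3 * (1.0 - v)
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def integrate_states(
    spec: DCMSpec,
    hemo: HemodynamicParameters,
    U: np.ndarray,
    dt: float,
    output_dt: float = None,
):
    """Integrate neural + balloon states over inputs U (m x T) sampled on
    the output grid (spacing ``output_dt``, default = dt).  When dt is a
    finer step than the output grid, the inputs are held piecewise constant
    over each output interval and the states are subsampled back onto the
    output grid.  Returns (z, v, q) each (n, T).
    """
    if dt > 0.1 + 1e-12:
        raise ValueError("dt must be <= 0.1 s for the fixed-step integrator")
    U = np.asarray(U, dtype=float)
    if output_dt is None:
        output_dt = dt
    substeps = int(round(output_dt / dt))
    if abs(substeps * dt - output_dt) > 1e-9:
        raise ValueError("dt must divide the output sample interval")
    U_fine = np.repeat(U, substeps, axis=1) if substeps > 1 else U
    n = spec.n_regions
    ks, ga, tau, al, E0 = hemo.per_region(n)
    z, v, q, bad = integrate_batch(
        spec.A[None],
        spec.B[None],
        spec.C[None],
        ks[None],
        ga[None],
        tau[None],
        al[None],
        E0[None],
        U_fine,
        float(dt),
    )
    if bad[0]:
        raise RuntimeError(
            f"state blow-up during integration of {spec.name}; "
            "unstable coupling parameters"
        )
    sl = slice(substeps - 1, None, substeps)
    return z[0][:, sl], v[0][:, sl], q[0][:, sl]


def integrate_dcm(
    spec: DCMSpec,
    hemo: HemodynamicParameters,
    obs_model,
    U: np.ndarray,
    dt: float = 0.1,
    output_dt: float = 0.1,
    with_bold: bool = False,
    bold_model: BOLDObservationModel = None,
):
    """Run the full generative model over the session.

    ``U`` is the (n_inputs, T) stimulus matrix on the output grid (10 Hz for
    the study, ``output_dt`` = 0.1 s); the integrator runs at fixed step
    ``dt`` <= output_dt.  Returns the predicted fNIRS OD series
    (2*nchan, T) and, optionally, the BOLD region series (n, T).
    """
    z, v, q = integrate_states(spec, hemo, U, dt, output_dt=output_dt)
    dHc, dQc = chromophore_changes(v, q, hemo)
    y = observe_fnirs(dHc, dQc, obs_model)
    if with_bold:
        return y, observe_bold(v, q, bold_model)
    return y
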