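"""Synthetic twin datasets and the recovery harness.

Generates complete fNIRS + BOLD recordings from a known ground-truth DCM
under the study's block design (24 blocks of 9 s, >= 13 s rest, 11.5 min at
10 Hz, 9 channels x 2 wavelengths), with physiological noise in the
Mayer-wave and cardiac bands, white noise and occasional motion spikes.
The recovery harness runs the full analysis chain -- preprocessing, trial
averaging, inversion of all 13 models for both modalities, model selection
and averaging, and the cross-modality agreement statistics -- against the
known truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np

from . import compare, preprocess
from .design import BlockDesign, build_block_design
from .generative import (
    DCMSpec,
    HemodynamicParameters,
    FNIRSObservationModel,
    BOLDObservationModel,
    integrate_states,
    chromophore_changes,
    observe_fnirs,
    observe_bold,
    REGIONS,
    INPUTS,
)
from .inversion import PriorSpec, pack_parameters, fit_dcm
from .preprocess import ChannelTimeSeries

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "ground_truth_spec",
    "default_observation_model",
    "default_region_centres",
    "simulate_experiment",
    "preprocess_for_dcm",
    "fit_model_space",
    "recovery_experiment",
]


def ground_truth_spec() -> DCMSpec:
    """Default ground truth: model-8 structure (NV modulates STS->IFG) with
    stable, identifiable coupling strengths (Hz)."""
    n = len(REGIONS)
    ifg, sts, tpj = (REGIONS.index(r) for r in ("IFG", "STS", "TPJ"))
    A = -0.5 * np.eye(n)
    A[tpj, sts] = 0.3  # STS->TPJ
    A[sts, tpj] = 0.2
    A[ifg, sts] = 0.3  # STS->IFG
    A[sts, ifg] = 0.2
    A_mask = A != 0
    np.fill_diagonal(A_mask, True)
    B = np.zeros((len(INPUTS), n, n))
    B[INPUTS.index("NV"), ifg, sts] = 0.4
    C = np.zeros((n, len(INPUTS)))
    C[sts, :] = 0.3
    return DCMSpec(A=A, B=B, C=C, A_mask=A_mask, name="truth_model_8")


def default_region_centres() -> dict:
    """Cortical source-region centres (mm) in the slab-head frame, each
    lying under a distinct part of the probe."""
    return {"IFG": (-8.0, 0.0, 12.0), "STS": (20.0, 0.0, 12.0), "TPJ": (8.0, 20.0, 12.0)}


@lru_cache(maxsize=2)
def default_observation_model(edge_mm: float = 4.0) -> FNIRSObservationModel:
    """Channels x regions optics observation built end-to-end: slab head
    mesh, fixture probe, FEM photon transport, PMDF rows condensed onto
    4 mm source regions.  The region sensitivity is normalized by its
    largest entry so the free scaling k is ~1 for matched simulations.

    Cached: the recovery harness reuses one model across runs.
    """
    from .mesh import build_layered_slab_mesh, build_fixture_array
    from .optics import (
        channel_sensitivity_matrix,
        default_coefficients,
        nodes_in_sphere,
        region_sensitivity,
    )

    mesh = build_layered_slab_mesh(
        (80.0, 64.0, 32.0), (5.0, 2.0, 25.0), edge_mm, origin=(-32.0, -32.0, 0.0)
    )
    array = build_fixture_array()
    coeffs = default_coefficients()
    S = channel_sensitivity_matrix(mesh, array, coeffs)
    regions = {
        name: nodes_in_sphere(mesh, centre, 4.0)
        for name, centre in default_region_centres().items()
    }
    R, names = region_sensitivity(S, regions)
    order = [names.index(r) for r in REGIONS]
    R = R[:, :, order] / np.abs(R).max()
    eps = preprocess.default_extinction_matrix()  # (wavelength, [HbO, HbR])
    return FNIRSObservationModel(
        wavelengths=tuple(S.wavelengths),
        eps_H=eps[:, 0],
        eps_Q=eps[:, 1],
        S0=R,
        k=1.0,
    )


@dataclass
class SimulationConfig:
    """Ground truth, design and noise settings for one synthetic session."""

    seed: int  # drives the noise realization only
    design_seed: int = 1234  # block order/jitter; fixed protocol by default
    spec: DCMSpec = field(default_factory=ground_truth_spec)
    hemo: HemodynamicParameters = field(default_factory=HemodynamicParameters)
    n_per_condition: int = 12
    block_duration: float = 9.0
    min_rest: float = 13.0
    session: float = 690.0
    sampling_rate: float = 10.0
    snr: float = 5.0  # clean-signal SD / white-noise SD on the best channel
    mayer_hz: float = 0.1
    mayer_rel_amplitude: float = 2.0  # x white-noise SD
    cardiac_hz: float = 1.2
    cardiac_rel_amplitude: float = 2.0
    spike_rate_per_min: float = 0.5
    spike_magnitude_uM: tuple = (5.0, 15.0)
    spike_decay_s: float = 1.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("snr", "mayer_rel_amplitude", "cardiac_rel_amplitude",
                     "spike_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def digest(self) -> str:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if not isinstance(v, (np.ndarray, dict))
        }
        payload["spec"] = self.spec.to_json()
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticDataset:
    """One simulated twin session with its stored noise decomposition."""

    config: SimulationConfig
    design: BlockDesign
    clean_od: np.ndarray  # (2*nchan, T)
    noise_od: np.ndarray
    clean_bold: np.ndarray  # (n_regions, T)
    noise_bold: np.ndarray
    obs_model: FNIRSObservationModel
    truth: dict
    provenance: str = ""

    @property
    def noisy_od(self) -> np.ndarray:
        return self.clean_od + self.noise_od

    @property
    def noisy_bold(self) -> np.ndarray:
        return self.clean_bold + self.noise_bold

    def od_series(self, noisy: bool = True) -> ChannelTimeSeries:
        vals = self.noisy_od if noisy else self.clean_od
        nch = self.obs_model.n_channels
        meta = [
            f"ch{c + 1}:{int(wl)}nm"
            for wl in self.obs_model.wavelengths
            for c in range(nch)
        ]
        return ChannelTimeSeries(
            vals, self.config.sampling_rate, "optical_density", meta
        )


def simulate_experiment(config: SimulationConfig, obs_model=None) -> SyntheticDataset:
    """Simulate one session: seeded design, DCM integration, fNIRS/BOLD
    observation, and seeded additive noise (stored separately from the
    clean series)."""
    rng = np.random.default_rng(config.seed)
    design = build_block_design(
        n_per_condition=config.n_per_condition,
        duration=config.block_duration,
        min_rest=config.min_rest,
        session=config.session,
        seed=config.design_seed,
        sampling_rate=config.sampling_rate,
    )
    if obs_model is None:
        obs_model = default_observation_model()
    fs = config.sampling_rate
    U = design.input_functions(fs)
    z, v, q = integrate_states(config.spec, config.hemo, U, 1.0 / fs)
    if np.abs(z).max() > 1e3:
        raise RuntimeError("unstable ground-truth parameters")
    dHc, dQc = chromophore_changes(v, q, config.hemo)
    clean_od = observe_fnirs(dHc, dQc, obs_model)
    clean_bold = observe_bold(v, q, BOLDObservationModel(E0=float(np.atleast_1d(config.hemo.E0)[0])))

    T = clean_od.shape[1]
    t = np.arange(T) / fs
    n_rows = clean_od.shape[0]
    sd_best = clean_od.std(axis=1).max()
    sigma_w = sd_best / config.snr if config.snr > 0 else 0.0

    noise = rng.normal(0.0, sigma_w, size=clean_od.shape)
    for row in range(n_rows):
        f_m = config.mayer_hz * (1.0 + 0.1 * rng.standard_normal())
        f_c = config.cardiac_hz * (1.0 + 0.1 * rng.standard_normal())
        noise[row] += (
            config.mayer_rel_amplitude
            * sigma_w
            * np.sin(2 * np.pi * f_m * t + rng.uniform(0, 2 * np.pi))
        )
        noise[row] += (
            config.cardiac_rel_amplitude
            * sigma_w
            * np.sin(2 * np.pi * f_c * t + rng.uniform(0, 2 * np.pi))
        )
    # motion spikes: step + exponential decay, coherent across rows of a
    # channel (both wavelengths move together, as real optode motion does)
    nch = obs_model.n_channels
    ext = preprocess.default_extinction_matrix()
    n_spikes = rng.poisson(config.spike_rate_per_min * config.session / 60.0)
    spike_times = np.sort(rng.uniform(5.0, config.session - 5.0, size=n_spikes))
    for ts in spike_times:
        ch = int(rng.integers(0, nch))
        mag = rng.uniform(*config.spike_magnitude_uM) * rng.choice([-1.0, 1.0])
        i0 = int(round(ts * fs))
        decay = np.exp(-(t[i0:] - t[i0]) / config.spike_decay_s)
        for w in range(len(obs_model.wavelengths)):
            # OD excursion equivalent to `mag` uM of oxy-Hb at this channel
            amp = mag * ext[w, 0] * 20.0 * preprocess.DPF_DEFAULT
            noise[w * nch + ch, i0:] += amp * decay

    sd_bold = clean_bold.std(axis=1).max()
    noise_bold = rng.normal(
        0.0, sd_bold / config.snr if config.snr > 0 else 0.0, size=clean_bold.shape
    )

    truth = {
        "A": config.spec.A.tolist(),
        "B": config.spec.B.tolist(),
        "C": config.spec.C.tolist(),
        "k": obs_model.k,
    }
    return SyntheticDataset(
        config,
        design,
        clean_od,
        noise,
        clean_bold,
        noise_bold,
        obs_model,
        truth,
        provenance=config.digest(),
    )


# ---------------------------------------------------------------------------
# The analysis chain on one dataset
# ---------------------------------------------------------------------------

EPOCH_WINDOW = (-2.0, 22.0)
# the inversion integrates the full session design, so no averaged input
# history is needed beyond the epoch window itself
INPUT_LEADIN = 0.0


def preprocess_for_dcm(dataset: SyntheticDataset):
    """Condition the synthetic recording for inversion.

    Motion artifacts are detected on the MBLL oxy-Hb series (3 uM / 1 s
    moving-SD rule, flagged segments dilated to cover spike decay tails)
    and corrected on the OD channels; the corrected series is then trial
    averaged.  The Butterworth filter bank is deliberately not applied in
    the DCM path: the generative prediction is unfiltered, the Mayer notch
    overlaps the evoked-response band, and averaging 12 jittered trials
    already suppresses the oscillatory physiological noise.  Returns
    (fnirs EpochAverage, bold EpochAverage).
    """
    od = dataset.od_series(noisy=True)
    nch = dataset.obs_model.n_channels
    hbo = preprocess.mbll(od)
    mask_conc = preprocess.detect_artifacts(
        ChannelTimeSeries(
            hbo.values[:nch], od.sampling_rate, "concentration", hbo.channel_meta[:nch]
        ),
        pad_forward_s=3.0,
        pad_backward_s=0.5,
    )
    od_mask = preprocess.ArtifactMask(
        np.tile(mask_conc.flags, (2, 1)), mask_conc.window_s, mask_conc.threshold_uM
    )
    od_corr = preprocess.spline_correct(od, od_mask)
    fnirs_avg = preprocess.epoch_average(
        od_corr, dataset.design, EPOCH_WINDOW, input_leadin_s=INPUT_LEADIN
    )
    bold = ChannelTimeSeries(
        dataset.noisy_bold, dataset.config.sampling_rate, "concentration",
        list(REGIONS), units="bold",
    )
    bold_avg = preprocess.epoch_average(
        bold, dataset.design, EPOCH_WINDOW, input_leadin_s=INPUT_LEADIN
    )
    return fnirs_avg, bold_avg


def fit_model_space(
    dataset: SyntheticDataset,
    space=None,
    priors: PriorSpec = None,
    modality: str = "fnirs",
    max_iter: int = 32,
    epoch_averages=None,
):
    """Invert every model of the space against one dataset; returns the
    list of PosteriorFit in model order."""
    if space is None:
        space = compare.build_model_space()
    if priors is None:
        priors = PriorSpec()
    fnirs_avg, bold_avg = epoch_averages or preprocess_for_dcm(dataset)
    avg = fnirs_avg if modality == "fnirs" else bold_avg
    U = dataset.design.input_functions(dataset.config.sampling_rate)
    fits = []
    for spec in space.models:
        packing = pack_parameters(spec, priors, mode=modality)
        fit = fit_dcm(
            avg,
            packing,
            dataset.config.hemo,
            U,
            obs_model=dataset.obs_model if modality == "fnirs" else None,
            priors=priors,
            max_iter=max_iter,
            fd_scheme="forward",
        )
        fits.append(fit)
    return fits


def _truth_coverage(fit, truth_spec: DCMSpec, level: float = 0.9):
    """Coverage of the true nonzero A/B/C values by the fit's credible
    intervals; returns (n_covered, n_checked)."""
    ci = fit.credible_interval(level)
    idx = {nm: i for i, nm in enumerate(fit.names)}
    n = truth_spec.n_regions
    checked, covered = 0, 0

    def check(name, true_val):
        nonlocal checked, covered
        if name not in idx:
            return
        lo, hi = ci[idx[name]]
        checked += 1
        covered += int(lo <= true_val <= hi)

    for i in range(n):
        for j in range(n):
            if i == j:
                # self-connections are log-scalings of -0.5
                check(
                    f"A_self:{truth_spec.regions[i]}",
                    float(np.log(truth_spec.A[i, i] / -0.5)),
                )
            elif truth_spec.A_mask[i, j]:
                check(
                    f"A:{truth_spec.regions[j]}->{truth_spec.regions[i]}",
                    float(truth_spec.A[i, j]),
                )
    for k in range(truth_spec.n_inputs):
        for i in range(n):
            for j in range(n):
                if truth_spec.B_mask[k, i, j]:
                    check(
                        f"B:{truth_spec.inputs[k]}:{truth_spec.regions[j]}->{truth_spec.regions[i]}",
                        float(truth_spec.B[k, i, j]),
                    )
            if truth_spec.C_mask[i, k]:
                check(
                    f"C:{truth_spec.inputs[k]}->{truth_spec.regions[i]}",
                    float(truth_spec.C[i, k]),
                )
    return covered, checked


def recovery_experiment(
    config: SimulationConfig = None,
    n_runs: int = 20,
    seed: int = 0,
    modalities=("fnirs", "bold"),
    max_iter: int = 32,
    n_dual: int = None,
) -> dict:
    """Run the in-silico validation: repeated simulate -> preprocess ->
    invert 13 models per modality -> BMS/BMA -> agreement statistics.

    Returns a JSON-serializable report with, per run, the selected model,
    truth-parameter coverage and cross-modality log-evidence correlation,
    plus pooled summaries (selection hit rate, top-2 rate, pooled 90% CI
    coverage of nonzero A/B/C, robust-regression stats between the two
    modalities' BMA vectors).

    ``n_dual`` limits how many of the runs invert the second modality as
    well (the rest run the first modality only); cross-modality statistics
    then pool over the dual runs.  Default: all runs fit every modality.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    space = compare.build_model_space()
    truth_index = 7  # model_8 generates the data
    base = config or SimulationConfig(seed=0)
    truth_spec = base.spec

    runs = []
    failures = 0
    for run in range(n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        cfg_kwargs = {k: v for k, v in base.__dict__.items()}
        cfg_kwargs["seed"] = run_seed
        cfg = SimulationConfig(**cfg_kwargs)
        try:
            ds = simulate_experiment(cfg)
            averages = preprocess_for_dcm(ds)
            rec = {"seed": run_seed}
            bma_by_mod, F_by_mod, per_model_by_mod = {}, {}, {}
            run_modalities = (
                modalities
                if n_dual is None or run < n_dual
                else modalities[:1]
            )
            for modality in run_modalities:
                fits = fit_model_space(
                    ds, space, modality=modality, max_iter=max_iter,
                    epoch_averages=averages,
                )
                sel = compare.bms(fits, [m.name for m in space.models])
                avg_post = compare.bma(fits, sel)
                cov, tot = _truth_coverage(fits[truth_index], truth_spec)
                order = np.argsort(sel.free_energy)[::-1]
                rec[modality] = {
                    "selected": sel.best_index,
                    "selected_name": sel.best_name,
                    "truth_rank": int(np.nonzero(order == truth_index)[0][0]) + 1,
                    "free_energy": sel.free_energy.tolist(),
                    "coverage": [cov, tot],
                }
                bma_by_mod[modality] = avg_post
                F_by_mod[modality] = sel.free_energy
                # per-model coupling estimates: the 91/26/8/8-point vectors
                # the cross-method regressions compare
                per_model = {}
                for spec_m, fit in zip(space.models, fits):
                    for nm, mu in zip(fit.names, fit.mean):
                        if nm.startswith(("A", "B", "C")):
                            per_model[f"{spec_m.name}:{nm}"] = float(mu)
                per_model_by_mod[modality] = per_model
            if len(run_modalities) == 2:
                r, p = compare.pearson(*(F_by_mod[m] for m in run_modalities))
                rec["log_evidence_pearson_r"] = r
                rec["bma_vectors"] = {
                    m: bma_by_mod[m].as_dict() for m in run_modalities
                }
                rec["per_model_estimates"] = {
                    m: per_model_by_mod[m] for m in run_modalities
                }
            runs.append(rec)
        except Exception as exc:  # individual run failures are logged, not fatal
            failures += 1
            runs.append({"seed": run_seed, "error": f"{type(exc).__name__}: {exc}"})

    ok = [r for r in runs if "error" not in r]
    report = {
        "n_runs": n_runs,
        "n_failed": failures,
        "seed": seed,
        "snr": base.snr,
        "config_digest": base.digest(),
        "runs": runs,
    }
    for modality in modalities:
        good = [r[modality] for r in ok if modality in r]
        if not good:
            continue
        hits = np.mean([g["selected"] == truth_index for g in good])
        top2 = np.mean([g["truth_rank"] <= 2 for g in good])
        cov = np.array([g["coverage"] for g in good], dtype=float).sum(axis=0)
        report[modality] = {
            "selection_hit_rate": float(hits),
            "top2_rate": float(top2),
            "coverage_fraction": float(cov[0] / cov[1]) if cov[1] else float("nan"),
        }
    ok_dual = [r for r in ok if "log_evidence_pearson_r" in r]
    if ok_dual:
        rs = [r["log_evidence_pearson_r"] for r in ok_dual]
        report["log_evidence_pearson_r_median"] = float(np.median(rs))
        # per-run robust regressions between the modalities' per-model
        # coupling estimates, split by parameter class (91 intrinsic / 26
        # input / 8 V- / 8 NV-modulation points per run, the cross-method
        # agreement analysis); summarized by medians across runs
        mod_a, mod_b = modalities

        def _cls(nm):
            # nm is "model_k:<param>"
            param = nm.split(":", 1)[1]
            if param.startswith("A"):
                return "A"
            if param.startswith("C"):
                return "C"
            if param.startswith("B:V"):
                return "B_V"
            if param.startswith("B:NV"):
                return "B_NV"
            return None

        per_run_stats = {c: [] for c in ("A", "C", "B_V", "B_NV")}
        for r in ok_dual:
            va = r["per_model_estimates"][mod_a]
            vb = r["per_model_estimates"][mod_b]
            buckets = {c: ([], []) for c in per_run_stats}
            for nm, x in va.items():
                c = _cls(nm)
                if c is not None and nm in vb:
                    buckets[c][0].append(x)
                    buckets[c][1].append(vb[nm])
            for c, (xs, ys) in buckets.items():
                if len(xs) >= 3 and np.std(xs) > 0:
                    rr = compare.robust_regression(np.array(xs), np.array(ys))
                    per_run_stats[c].append(
                        {"slope": rr.slope, "F": rr.f_statistic, "p": rr.p_value,
                         "R2": rr.r_squared, "n": len(xs)}
                    )
        report["bma_agreement"] = {}
        for c, stats in per_run_stats.items():
            if stats:
                report["bma_agreement"][c] = {
                    "R2_median": float(np.median([s["R2"] for s in stats])),
                    "slope_median": float(np.median([s["slope"] for s in stats])),
                    "n_points": stats[0]["n"],
                    "n_runs": len(stats),
                }
    return report
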