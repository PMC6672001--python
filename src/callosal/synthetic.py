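"""Synthetic data with planted ground truth for every pipeline stage.

Each generator emulates one acquisition of the study design — band-limited
correlated ROI BOLD signals (150 timepoints at TR 2 s, 0.01-0.1 Hz),
single-shell DWI at b = 800 s mm^-2 with 60 directions, dark-myelin annular
axon images at 7 nm/px, 10 kHz extracellular traces with planted biphasic
spikes, and behavioural trial tables — and returns the generated data
together with a :class:`GroundTruthBundle` so downstream estimates can be
checked by parameter recovery.  Every generator is deterministic given its
seed.

ROI signals are built by band-pass filtering white noise, standardising,
and imposing the target correlation with a Cholesky factor, which plants
the correlation exactly in expectation.  DWI noise is Gaussian with
s.d. S0/SNR by default (a ``rician`` switch exists) so the log-linear fit
stays unbiased in the recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fc import ROITimeSeriesSet, bandpass
from .io import Acquisition

__all__ = [
    "GroundTruthBundle",
    "gen_roi_timeseries",
    "make_acquisition",
    "gen_dwi",
    "tensor_from_principal",
    "AxonSpec",
    "random_axon_specs",
    "gen_em_image",
    "gen_mea_trace",
    "gen_behaviour_tables",
]


@dataclass
class GroundTruthBundle:
    """Planted truth travelling with a generated dataset."""

    modality: str
    truth: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.truth[key]


# ---------------------------------------------------------------- rsfMRI


def _check_correlation(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-12):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-12):
        raise ValidationError("correlation matrix must have unit diagonal")
    try:
        np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        raise ValidationError("correlation matrix is not positive-definite") from None
    return c


def gen_roi_timeseries(
    n_subjects_per_group: dict[str, int],
    roi_labels: list[str],
    group_correlations: dict[str, np.ndarray],
    n_timepoints: int = 150,
    sampling_interval_s: float = 2.0,
    band: tuple[float, float] = (0.01, 0.1),
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[ROITimeSeriesSet], GroundTruthBundle]:
    """Band-limited correlated ROI signals with a per-group planted correlation.

    Latent signals are white noise band-passed to ``band``, standardised,
    then mixed with the Cholesky factor of the group's correlation matrix;
    a ``noise_fraction`` of white-noise variance is added on top.
    """
    if n_timepoints <= 0:
        raise ValidationError("n_timepoints must be positive")
    if n_timepoints < 8:
        raise ValidationError("n_timepoints must be >=8 for filtering")
    if not 0.0 <= noise_fraction < 1.0:
        raise ValidationError("noise_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_roi = len(roi_labels)
    chol = {}
    for g, c in group_correlations.items():
        c = _check_correlation(c)
        if c.shape[0] != n_roi:
            raise ValidationError("correlation matrix size must match ROI count")
        chol[g] = np.linalg.cholesky(c)
    subjects: list[ROITimeSeriesSet] = []
    truth = {"correlations": {g: np.asarray(c, dtype=float)
                              for g, c in group_correlations.items()}}
    for group, n_sub in n_subjects_per_group.items():
        for i in range(n_sub):
            white = rng.standard_normal((n_roi, n_timepoints))
            latent = bandpass(white, sampling_interval_s, *band)
            latent /= latent.std(axis=1, keepdims=True)
            mixed = chol[group] @ latent
            if noise_fraction > 0:
                extra = rng.standard_normal((n_roi, n_timepoints))
                mixed = (np.sqrt(1 - noise_fraction) * mixed
                         + np.sqrt(noise_fraction) * extra)
            subjects.append(ROITimeSeriesSet(
                f"{group}{i:03d}", group, list(roi_labels), mixed,
                sampling_interval_s))
    return subjects, GroundTruthBundle("rsfmri", truth)


# ------------------------------------------------------------------ DWI


def make_acquisition(b_value: float = 800.0, n_directions: int = 60,
                     n_b0: int = 1, seed: int = 7) -> Acquisition:
    """Single-shell acquisition with quasi-uniform unit directions.

    Directions are drawn from a Fibonacci sphere (deterministic for a given
    count) so any >=6 of them are non-collinear.
    """
    i = np.arange(n_directions)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_directions
    r = np.sqrt(1.0 - z ** 2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.r_[np.zeros(n_b0), np.full(n_directions, b_value)]
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return Acquisition(bvals, bvecs)


def tensor_from_principal(eigenvalues: np.ndarray,
                          principal_direction: np.ndarray | None = None) -> np.ndarray:
    """Symmetric tensors from eigenvalues (descending) and the λ1 direction.

    Secondary eigenvectors are completed by Gram-Schmidt; for λ2 != λ3 the
    in-plane frame is therefore a convention, which leaves all rotationally
    invariant scalars unaffected.  Broadcasts over leading axes.
    """
    ev = np.asarray(eigenvalues, dtype=float).reshape(-1, 3)
    if np.any(ev < 0):
        raise ValidationError("eigenvalues must be non-negative")
    if principal_direction is None:
        e1 = np.tile(np.array([1.0, 0.0, 0.0]), (ev.shape[0], 1))
    else:
        e1 = np.asarray(principal_direction, dtype=float).reshape(-1, 3)
        if e1.shape[0] == 1 and ev.shape[0] > 1:
            e1 = np.broadcast_to(e1, (ev.shape[0], 3)).copy()
        norms = np.linalg.norm(e1, axis=-1, keepdims=True)
        if np.any(norms == 0):
            raise ValidationError("principal direction cannot be zero")
        e1 = e1 / norms
    helper = np.where(np.abs(e1[:, [0]]) < 0.9,
                      np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    e2 = helper - (helper * e1).sum(-1, keepdims=True) * e1
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    frames = np.stack([e1, e2, e3], axis=-2)        # (n, 3, 3) rows = eigvecs
    d = np.einsum("ni,nij,nik->njk", ev, frames, frames)
    out_shape = np.asarray(eigenvalues).shape[:-1] + (3, 3)
    return d.reshape(out_shape)


def gen_dwi(
    eigenvalue_field: np.ndarray,
    principal_direction_field: np.ndarray | None,
    s0: float,
    acquisition: Acquisition,
    snr: float | None = None,
    seed: int = 0,
    noise: str = "gaussian",
) -> tuple[np.ndarray, GroundTruthBundle]:
    """Noiseless tensor-model signals S = S0·exp(−b·ĝᵀDĝ), plus optional noise.

    ``snr=None`` (infinite) returns the exact model values; a finite SNR adds
    noise of s.d. S0/snr, Gaussian by default or Rician with ``noise="rician"``.
    """
    ev = np.asarray(eigenvalue_field, dtype=float)
    if ev.shape[-1] != 3:
        raise ValidationError("eigenvalue field must end with axis of length 3")
    d = tensor_from_principal(ev, principal_direction_field)
    b = acquisition.bvals
    g = acquisition.bvecs
    quad = np.einsum("mi,...ij,mj->...m", g, d, g)
    signal = s0 * np.exp(-b * quad)
    truth = {"eigenvalues": ev, "tensor": d, "s0": s0}
    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise ValidationError("snr must be positive")
        rng = np.random.default_rng(seed)
        sd = s0 / snr
        if noise == "gaussian":
            signal = signal + rng.normal(0.0, sd, signal.shape)
        elif noise == "rician":
            signal = np.hypot(signal + rng.normal(0.0, sd, signal.shape),
                              rng.normal(0.0, sd, signal.shape))
        else:
            raise ValidationError(f"unknown noise model {noise!r}")
    return signal, GroundTruthBundle("dwi", truth)


# ------------------------------------------------------------------- EM


@dataclass
class AxonSpec:
    """One annular axon: centre (row, col) px, inner/outer diameters px."""

    centre_px: tuple[float, float]
    d_px: float
    D_px: float

    def __post_init__(self):
        if not 0 < self.d_px < self.D_px:
            raise ValidationError(f"need 0 < d < D, got d={self.d_px}, D={self.D_px}")


def random_axon_specs(n: int, rng: np.random.Generator,
                      d_range_px: tuple[float, float] = (30.0, 90.0),
                      g_range: tuple[float, float] = (0.55, 0.85),
                      margin_px: float = 8.0) -> tuple[list[AxonSpec], tuple[int, int]]:
    """Non-overlapping axons on a jittered grid; returns (specs, image size)."""
    d = rng.uniform(*d_range_px, size=n)
    g = rng.uniform(*g_range, size=n)
    dd = d / g
    pitch = float(dd.max() + 2 * margin_px)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    specs = []
    for i in range(n):
        r, c = divmod(i, cols)
        jit = rng.uniform(-margin_px / 2, margin_px / 2, size=2)
        centre = (pitch * (r + 0.5) + jit[0], pitch * (c + 0.5) + jit[1])
        specs.append(AxonSpec(centre, float(d[i]), float(dd[i])))
    size = (int(np.ceil(pitch * rows)), int(np.ceil(pitch * cols)))
    return specs, size


def gen_em_image(
    axon_specs: list[AxonSpec],
    image_size: tuple[int, int],
    pixel_size_nm: float = 7.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 200.0,
    myelin: float = 60.0,
    enforce_non_overlap: bool = True,
) -> tuple[np.ndarray, GroundTruthBundle]:
    """Render dark myelin annuli on a light background with <=1 px soft edges.

    Each annulus occupies radii (d/2, D/2) around its centre; edges use a
    linear 1-px coverage ramp (anti-aliasing).  Overlap between annuli is
    rejected when ``enforce_non_overlap``.
    """
    if pixel_size_nm <= 0:
        raise ValidationError("pixel size must be positive")
    if enforce_non_overlap and len(axon_specs) > 1:
        centres = np.array([s.centre_px for s in axon_specs])
        radii = np.array([s.D_px / 2 for s in axon_specs])
        diff = centres[:, None, :] - centres[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        lim = radii[:, None] + radii[None, :]
        clash = (dist < lim) & ~np.eye(len(axon_specs), dtype=bool)
        if clash.any():
            i, j = np.argwhere(clash)[0]
            raise ValidationError(f"axons {i} and {j} overlap")
    img = np.full(image_size, background, dtype=float)
    um = pixel_size_nm / 1000.0
    truth_rows = []
    for k, spec in enumerate(axon_specs):
        r_in, r_out = spec.d_px / 2.0, spec.D_px / 2.0
        cy, cx = spec.centre_px
        pad = int(np.ceil(r_out)) + 2
        y0, y1 = max(0, int(cy) - pad), min(image_size[0], int(cy) + pad + 1)
        x0, x1 = max(0, int(cx) - pad), min(image_size[1], int(cx) + pad + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(yy - cy, xx - cx)
        cover = (np.clip(r_out - dist + 0.5, 0.0, 1.0)
                 - np.clip(r_in - dist + 0.5, 0.0, 1.0))
        img[y0:y1, x0:x1] += (myelin - background) * cover
        truth_rows.append({
            "axon_id": k, "row_px": cy, "col_px": cx,
            "d_px": spec.d_px, "D_px": spec.D_px,
            "d_um": spec.d_px * um, "D_um": spec.D_px * um,
            "g_ratio": spec.d_px / spec.D_px,
        })
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    truth = {"axons": pd.DataFrame(truth_rows), "pixel_size_nm": pixel_size_nm}
    return img, GroundTruthBundle("em", truth)


# ------------------------------------------------------------------ MEA


def _spike_template(sampling_hz: float) -> np.ndarray:
    """1 ms biphasic (dominant-negative) waveform with unit negative peak."""
    n = max(int(round(1.0e-3 * sampling_hz)), 4)
    t = np.arange(n) / sampling_hz
    w = (-np.exp(-0.5 * ((t - 0.3e-3) / 0.12e-3) ** 2)
         + 0.35 * np.exp(-0.5 * ((t - 0.7e-3) / 0.15e-3) ** 2))
    return w / np.abs(w.min())


def _scan_bursts(times: np.ndarray, min_spikes: int = 5,
                 max_isi_s: float = 0.050) -> list[tuple[float, float, int]]:
    out, i = [], 0
    isi = np.diff(times) < max_isi_s
    while i < isi.size:
        if isi[i]:
            j = i
            while j < isi.size and isi[j]:
                j += 1
            if j - i + 1 >= min_spikes:
                out.append((float(times[i]), float(times[j]), j - i + 1))
            i = j
        else:
            i += 1
    return out


def gen_mea_trace(
    duration_s: float,
    sampling_hz: float = 10_000.0,
    noise_sd: float = 1.0,
    spike_times_s=(),
    spike_amplitude_sd_multiples: float | np.ndarray = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthBundle]:
    """Gaussian baseline with biphasic spikes planted at the truth times.

    The negative peak of each planted spike is
    ``spike_amplitude_sd_multiples`` (scalar, or one value per spike) x
    ``noise_sd`` below baseline, landing on the sample nearest the requested
    time + 0.3 ms (the template's peak offset is recorded in the truth
    bundle for recovery scoring).
    """
    if sampling_hz < 1000:
        raise ValidationError("sampling rate must be >=1 kHz (waveform unrepresentable)")
    if duration_s < 0:
        raise ValidationError("duration must be non-negative")
    n = int(round(duration_s * sampling_hz))
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    spike_times = np.asarray(spike_times_s, dtype=float).ravel()
    order = np.argsort(spike_times)
    spike_times = spike_times[order]
    if spike_times.size and (spike_times[0] < 0 or spike_times[-1] >= duration_s):
        raise ValidationError("spike times must lie within [0, duration)")
    amps = np.asarray(spike_amplitude_sd_multiples, dtype=float)
    if amps.ndim == 0:
        amps = np.full(spike_times.shape, float(amps))
    else:
        if amps.size != spike_times.size:
            raise ValidationError("one amplitude per spike required")
        amps = amps.ravel()[order]
    template = _spike_template(sampling_hz)
    peak_offset = int(np.argmin(template))
    planted = []
    for t0, amp in zip(spike_times, amps):
        start = int(round(t0 * sampling_hz))
        stop = min(start + template.size, n)
        trace[start:stop] += amp * noise_sd * template[: stop - start]
        planted.append((start + peak_offset) / sampling_hz)
    planted_arr = np.asarray(planted)
    truth = {
        "spike_times_s": planted_arr,
        "requested_times_s": spike_times,
        "bursts": _scan_bursts(planted_arr),
        "noise_sd": noise_sd,
        "sampling_hz": sampling_hz,
    }
    return trace, GroundTruthBundle("mea", truth)


# ------------------------------------------------------------ behaviour


def gen_behaviour_tables(design: dict, seed: int = 0
                         ) -> tuple[dict[str, pd.DataFrame], GroundTruthBundle]:
    """Behavioural trial tables with planted index values.

    ``design`` keys (all optional, sensible study-scale defaults):

    * ``ppi``: {"true_ppi_per_db": {0: 0, 3: ..., ...}, "startle_sd": float,
      "n_trials": 10, "base_amplitude": 100, "subjects": ["s1", ...]}
    * ``exploration``: {"preference_index": float, "total_s": 60,
      "subjects": [...]}
    * ``visits``: {"alternation_probability": float, "walk_length": int,
      "subjects": [...]}
    * ``slips``: {"slip_probability": float, "n_steps": int, "subjects": [...]}
    * ``latency``: {"groups": {name: {"n_subjects": int,
      "trial_means": [...], "sd": float}}}

    The expected value of each downstream index equals the planted truth.
    """
    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}
    truth: dict = {}

    if "ppi" in design:
        d = design["ppi"]
        ppi = {float(k): float(v) for k, v in d["true_ppi_per_db"].items()}
        sd = float(d.get("startle_sd", 0.0))
        n_trials = int(d.get("n_trials", 10))
        base = float(d.get("base_amplitude", 100.0))
        if n_trials <= 0:
            raise ValidationError("n_trials must be positive")
        rows = []
        for subject in d.get("subjects", ["s1"]):
            for block, n_pa in ((1, 5), (3, 5)):
                for _ in range(n_pa):
                    rows.append((subject, block, "pulse_alone", 0.0,
                                 max(0.0, base + rng.normal(0, sd) if sd else base)))
            for _ in range(n_trials):
                rows.append((subject, 2, "pulse_alone", 0.0,
                             max(0.0, base + rng.normal(0, sd) if sd else base)))
            for db, p in ppi.items():
                mean_amp = base * (1.0 - p / 100.0)
                for _ in range(n_trials):
                    amp = mean_amp + rng.normal(0, sd) if sd else mean_amp
                    rows.append((subject, 2, "prepulse_pulse", db, max(0.0, amp)))
        tables["startle"] = pd.DataFrame(
            rows, columns=["subject_id", "block", "trial_type", "prepulse_db",
                           "amplitude"])
        truth["ppi_per_db"] = ppi

    if "exploration" in design:
        d = design["exploration"]
        p = float(d["preference_index"])
        total = float(d.get("total_s", 60.0))
        rows = [{"subject_id": s, "time_novel_s": total * p / 100.0,
                 "time_familiar_s": total * (1.0 - p / 100.0)}
                for s in d.get("subjects", ["s1"])]
        tables["exploration"] = pd.DataFrame(rows)
        truth["preference_index"] = p

    if "visits" in design:
        d = design["visits"]
        p_alt = float(d["alternation_probability"])
        if not 0.0 <= p_alt <= 1.0:
            raise ValidationError("alternation probability must lie in [0, 1]")
        length = int(d.get("walk_length", 30))
        rows = []
        for s in d.get("subjects", ["s1"]):
            seq = [int(rng.integers(1, 4))]
            seq.append(int(rng.choice([a for a in (1, 2, 3) if a != seq[0]])))
            while len(seq) < length:
                prev2, prev1 = seq[-2], seq[-1]
                third = ({1, 2, 3} - {prev1, prev2}).pop()
                nxt = third if rng.random() < p_alt else prev2
                seq.append(nxt)
            rows += [{"subject_id": s, "order": i, "arm": a}
                     for i, a in enumerate(seq)]
        tables["visits"] = pd.DataFrame(rows)
        truth["alternation_probability"] = p_alt

    if "slips" in design:
        d = design["slips"]
        p_slip = float(d["slip_probability"])
        if not 0.0 <= p_slip <= 1.0:
            raise ValidationError("slip probability must lie in [0, 1]")
        n_steps = int(d.get("n_steps", 30))
        rows = [{"subject_id": s, "n_slips": int(rng.binomial(n_steps, p_slip)),
                 "n_steps": n_steps}
                for s in d.get("subjects", ["s1"])]
        tables["slips"] = pd.DataFrame(rows)
        truth["slip_percentage"] = 100.0 * p_slip

    if "latency" in design:
        d = design["latency"]
        rows = []
        for group, spec in d["groups"].items():
            means = np.asarray(spec["trial_means"], dtype=float)
            sd = float(spec.get("sd", 0.0))
            for i in range(int(spec["n_subjects"])):
                offsets = rng.normal(0, sd) if sd else 0.0
                for trial, mu in enumerate(means, start=1):
                    noise = rng.normal(0, sd) if sd else 0.0
                    rows.append({"subject_id": f"{group}{i:02d}", "group": group,
                                 "trial": trial,
                                 "value": mu + 0.5 * offsets + noise})
        tables["latency"] = pd.DataFrame(rows)
        truth["latency_trial_means"] = {
            g: list(map(float, spec["trial_means"]))
            for g, spec in d["groups"].items()}

    return tables, GroundTruthBundle("behaviour", truth)
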