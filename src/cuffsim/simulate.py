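"""nCAP waveform bank, propagating source matrices, recordings and noise.

A naturally evoked compound action potential (nCAP) is modeled as a fixed
biphasic extracellular template (difference of two Gaussians: a sharp
depolarization lobe followed by a slower repolarization lobe) drawn from a
bank of 1000 jittered variants — 100 samples at 30 kHz with seeded
amplitude and time-offset jitter.  One event propagates along a chain of
nodes of Ranvier inside a single fascicle at a fixed conduction velocity
(default 60 m/s); each node's row in the source matrix J is the template
delayed by its axial travel time.  Recordings follow D = L·J, after which
Gaussian white noise scaled to a fraction of the global signal maximum is
added and the result is normalized to unit maximum absolute amplitude.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cuffsim.forward import Leadfield


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclasses.dataclass
class WaveformBank:
    """Bank of jittered noiseless nCAP templates (n_templates x n_samples)."""

    templates: np.ndarray
    sampling_rate: float  # Hz
    amplitudes: np.ndarray  # realized amplitude factors
    offsets: np.ndarray  # realized time offsets, samples
    seed: int

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    @property
    def n_samples(self) -> int:
        return self.templates.shape[1]


def biphasic_template(
    n_samples: int = 100,
    sampling_rate: float = 30000.0,
    peak_fraction: float = 0.5,
    depol_width_ms: float = 0.10,
    repol_width_ms: float = 0.25,
    repol_delay_ms: float = 0.25,
    repol_amplitude: float = 0.55,
) -> np.ndarray:
    """Base biphasic nCAP shape: fast negative-going depolarization lobe
    minus a slower, delayed repolarization lobe, peak-normalized to 1."""
    t = np.arange(n_samples) / sampling_rate * 1e3  # ms
    t0 = t[-1] * peak_fraction
    w = np.exp(-0.5 * ((t - t0) / depol_width_ms) ** 2)
    w = w - repol_amplitude * np.exp(
        -0.5 * ((t - t0 - repol_delay_ms) / repol_width_ms) ** 2
    )
    return w / np.abs(w).max()


def _shift_linear(w: np.ndarray, shift: float) -> np.ndarray:
    """Shift a sampled waveform by a (fractional) number of samples,
    zero-filling at the edges."""
    n = w.size
    return np.interp(np.arange(n) - shift, np.arange(n), w, left=0.0, right=0.0)


def generate_waveform_bank(
    seed: int = 0,
    n_templates: int = 1000,
    n_samples: int = 100,
    sampling_rate: float = 30000.0,
    amplitude_jitter: float = 0.1,
    offset_jitter: float = 3.0,
    base_template: np.ndarray | None = None,
) -> WaveformBank:
    """Generate the jittered template bank; bit-identical under one seed.

    Amplitudes are Uniform(1-a, 1+a); offsets Uniform(-o, +o) samples
    applied by linear interpolation.  Offsets large enough to push the
    waveform's support out of the window are a configuration error.
    """
    if n_templates < 1 or n_samples < 2:
        raise SimulationError("need n_templates >= 1 and n_samples >= 2")
    if not 0 <= amplitude_jitter < 1:
        raise SimulationError("amplitude_jitter must be in [0, 1)")
    base = (
        biphasic_template(n_samples, sampling_rate)
        if base_template is None
        else np.asarray(base_template, dtype=float)
    )
    if base.size != n_samples:
        raise SimulationError("base template length mismatch")
    if np.abs(base).max() > 0:
        support = np.flatnonzero(np.abs(base) > 1e-3 * np.abs(base).max())
        margin = min(support[0], n_samples - 1 - support[-1])
    else:
        margin = n_samples  # zero template: offsets cannot clip anything
    if offset_jitter < 0 or offset_jitter > margin:
        raise SimulationError(
            f"offset_jitter {offset_jitter} would clip the waveform "
            f"(margin {margin} samples)"
        )
    rng = np.random.default_rng(seed)
    amplitudes = rng.uniform(1 - amplitude_jitter, 1 + amplitude_jitter, n_templates)
    offsets = rng.uniform(-offset_jitter, offset_jitter, n_templates)
    templates = np.empty((n_templates, n_samples))
    for i in range(n_templates):
        templates[i] = amplitudes[i] * _shift_linear(base, offsets[i])
    return WaveformBank(
        templates=templates,
        sampling_rate=sampling_rate,
        amplitudes=amplitudes,
        offsets=offsets,
        seed=seed,
    )


@dataclasses.dataclass(frozen=True)
class SourceEvent:
    """One nCAP: a template propagating along one fascicle's node chain."""

    fascicle_id: int
    node: int  # cross-section node index into the leadfield's node table
    template_index: int
    conduction_velocity: float = 60.0  # m/s
    node_spacing: float = 1.0  # mm between active nodes of Ranvier
    align_sample: int = 50  # sample at which the peak passes the cuff center

    def __post_init__(self) -> None:
        if self.conduction_velocity <= 0:
            raise SimulationError("conduction velocity must be positive")
        if self.node_spacing <= 0:
            raise SimulationError("node spacing must be positive")


@dataclasses.dataclass
class SourceMatrix:
    """Sparse row-block view of J (N source DOFs x T samples).

    Only the event's axial chain of nodes carries signal, so J is stored as
    the chain's column indices plus a dense (n_chain, T) block.
    """

    n_dofs: int
    n_samples: int
    columns: np.ndarray  # (n_chain,) leadfield column indices
    block: np.ndarray  # (n_chain, T)

    def to_dense(self) -> np.ndarray:
        J = np.zeros((self.n_dofs, self.n_samples))
        J[self.columns] = self.block
        return J


@dataclasses.dataclass
class Recording:
    """Multichannel cuff recording D (channels x T)."""

    data: np.ndarray
    sampling_rate: float = 30000.0
    noise_ratio: float = 0.0
    normalized: bool = False

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def build_source_matrix(
    event: SourceEvent, bank: WaveformBank, leadfield: Leadfield
) -> SourceMatrix:
    """Map one nCAP event onto the leadfield's source DOFs.

    The chain consists of the event node's registered axial slabs thinned
    to approximately the node-of-Ranvier spacing; the row at axial position
    z carries the template delayed by round((z - z_center) / v) samples
    (delays falling outside the window truncate to silence).
    """
    nodes = leadfield.nodes_of_fascicle(event.fascicle_id)
    if nodes.size == 0:
        raise SimulationError(
            f"fascicle {event.fascicle_id} has no registered source columns"
        )
    if event.node not in nodes:
        raise SimulationError(
            f"node {event.node} is not part of fascicle {event.fascicle_id}"
        )
    template = bank.templates[event.template_index]
    n_samples = template.size
    dz = float(np.diff(leadfield.slab_z).mean()) if leadfield.n_slabs > 1 else 1.0
    stride = max(1, int(round(event.node_spacing / dz)))
    slab_sel = np.arange(0, leadfield.n_slabs, stride)
    cols = event.node * leadfield.n_slabs + slab_sel
    z = leadfield.slab_z[slab_sel]
    v_mm_per_s = event.conduction_velocity * 1e3
    # floor(x + 0.5) keeps exactly uniform inter-node delays on the sample
    # grid when the travel time per node is an integer number of samples
    # (round-half-to-even would alternate at half-sample offsets)
    delays = np.floor(z / v_mm_per_s * bank.sampling_rate + 0.5).astype(int)
    # peak-at-center alignment: z = 0 keeps the template's native peak time
    shift_ref = template.size // 2
    block = np.zeros((cols.size, n_samples))
    for i, d in enumerate(delays):
        d_total = d + (event.align_sample - shift_ref)
        src_lo = max(0, -d_total)
        src_hi = min(n_samples, n_samples - d_total)
        if src_lo < src_hi:
            block[i, src_lo + d_total : src_hi + d_total] = template[src_lo:src_hi]
    return SourceMatrix(
        n_dofs=leadfield.matrix.shape[1],
        n_samples=n_samples,
        columns=cols,
        block=block,
    )


def synthesize_recording(leadfield: Leadfield, J: SourceMatrix) -> Recording:
    """D = L·J, exploiting J's sparse row-block structure."""
    if J.n_dofs != leadfield.matrix.shape[1]:
        raise SimulationError(
            f"shape mismatch: L has {leadfield.matrix.shape[1]} columns, "
            f"J has {J.n_dofs} rows"
        )
    data = leadfield.matrix[:, J.columns] @ J.block
    return Recording(data=data)


def add_noise(
    recording: Recording,
    noise_ratio: float,
    seed: int | np.random.Generator = 0,
    noise_mode: str = "amplitude",
) -> Recording:
    """Add i.i.d. Gaussian white noise scaled to the global signal maximum.

    ``amplitude`` mode (default): std(noise) = n * max|D| — the
    percent-of-amplitude reading used for in vivo SNR calibration.
    ``variance`` mode: var(noise) = n * max|D| (the literal variance
    formula; dimensionally inconsistent but kept selectable).
    """
    if noise_ratio < 0:
        raise SimulationError("noise ratio must be non-negative")
    if noise_ratio == 0:
        return Recording(
            data=recording.data.copy(),
            sampling_rate=recording.sampling_rate,
            noise_ratio=0.0,
            normalized=recording.normalized,
        )
    peak = np.abs(recording.data).max()
    if noise_mode == "amplitude":
        scale = noise_ratio * peak
    elif noise_mode == "variance":
        scale = np.sqrt(noise_ratio * peak)
    else:
        raise SimulationError(f"unknown noise_mode {noise_mode!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    noise = rng.normal(0.0, scale, size=recording.data.shape)
    return Recording(
        data=recording.data + noise,
        sampling_rate=recording.sampling_rate,
        noise_ratio=noise_ratio,
        normalized=False,
    )


def normalize_recording(recording: Recording) -> Recording:
    """Scale so the maximum absolute value over all channels and samples is 1."""
    peak = np.abs(recording.data).max()
    if peak == 0:
        raise SimulationError("cannot normalize an all-zero recording")
    return Recording(
        data=recording.data / peak,
        sampling_rate=recording.sampling_rate,
        noise_ratio=recording.noise_ratio,
        normalized=True,
    )
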