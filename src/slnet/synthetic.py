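"""Synthetic multichannel recordings with planted coupling structure.

Every downstream stage (SL, graphs, statistics, clustering) is exercised
against data whose ground truth is known: channels are partitioned into
modules, each module shares a band-limited latent source, and independent
noise is added per channel. Latent sources are band-pass filtered Gaussian
noise — the simplest process with controllable band content; a different
source model can be substituted by swapping :func:`_bandlimited_noise`.

Ground truth (the module partition) always travels with the generated data,
and seeds are explicit everywhere: the same spec and seed reproduce the same
session bit for bit.

Channel indices in specs are 1-based (Ch01..Ch19) to match the montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import signal

from .graph_metrics import AdjacencyMatrix
from .recordings import Event, MultichannelRecording, write_delimited

__all__ = [
    "CouplingSpec",
    "SessionSpec",
    "Session",
    "STUDY_TASKS",
    "MAIN_TASKS",
    "simulate_coupled_recording",
    "simulate_session",
    "make_graph_fixture",
    "make_planted_feature_table",
    "write_session",
]

#: The eight experimental conditions: equation-solving tasks at three
#: difficulty levels (ES, EM, EC), programming tasks at three levels
#: (PS, PM, PC), a fixation-cross control (Cr) and a subitizing control (Do).
STUDY_TASKS = ("ES", "EM", "EC", "PS", "PM", "PC", "Cr", "Do")

#: The six main tasks (controls excluded) used by the clustering stage.
MAIN_TASKS = ("ES", "EM", "EC", "PS", "PM", "PC")


@dataclass(frozen=True)
class CouplingSpec:
    """Planted coupling for one multichannel epoch.

    ``groups`` partitions a subset of the 1-based channel indices into
    modules sharing a latent source; channels in no group are independent
    noise. ``mixing`` weights the shared source per channel (scalar applies
    to all), ``noise_sd`` scales the independent additive Gaussian noise,
    and ``band`` is the (low, high) Hz content of the latent sources.
    """

    n_channels: int = 19
    groups: tuple[tuple[int, ...], ...] = ()
    mixing: float | tuple[float, ...] = 0.9
    noise_sd: float = 0.3
    band: tuple[float, float] = (8.0, 12.0)
    fs: float = 250.0
    duration: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        seen: set[int] = set()
        for g in self.groups:
            if len(g) == 0:
                raise ValueError("empty coupling group")
            for ch in g:
                if not 1 <= ch <= self.n_channels:
                    raise ValueError(f"channel {ch} outside 1..{self.n_channels}")
                if ch in seen:
                    raise ValueError(f"channel {ch} appears in two groups")
                seen.add(ch)
        mix = self.mixing_vector()
        if np.any((mix < 0) | (mix > 1)):
            raise ValueError("mixing coefficients must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        low, high = self.band
        if not 0 <= low < high:
            raise ValueError("invalid band")
        if self.fs <= 2 * high:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for band upper edge {high} Hz"
            )
        if self.duration * self.fs < 2:
            raise ValueError("duration too short")

    def mixing_vector(self) -> np.ndarray:
        if np.isscalar(self.mixing):
            return np.full(self.n_channels, float(self.mixing))
        mix = np.asarray(self.mixing, dtype=float)
        if mix.size != self.n_channels:
            raise ValueError("mixing length must equal n_channels")
        return mix


@dataclass(frozen=True)
class SessionSpec:
    """A full recording session: subjects x tasks x stimuli epochs.

    ``task_overrides`` maps a task label to replacement fields of the base
    :class:`CouplingSpec` (e.g. extra coupling groups for one task type),
    which is how condition effects are planted.
    """

    n_subjects: int = 16
    tasks: tuple[str, ...] = STUDY_TASKS
    stimuli_per_task: int = 20
    epoch_duration: float = 2.0
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    task_overrides: Mapping[str, Mapping] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.stimuli_per_task < 1:
            raise ValueError("n_subjects and stimuli_per_task must be >= 1")
        for t in self.tasks:
            if t not in STUDY_TASKS:
                raise ValueError(f"unknown task label {t!r}")
        for t in self.task_overrides:
            if t not in self.tasks:
                raise ValueError(f"override for task {t!r} not in tasks")

    def coupling_for(self, task: str) -> CouplingSpec:
        spec = replace(self.coupling, duration=self.epoch_duration)
        if task in self.task_overrides:
            spec = replace(spec, **dict(self.task_overrides[task]))
        return spec


@dataclass
class Session:
    """Generated epochs keyed by (subject, task, stimulus) plus ground truth."""

    spec: SessionSpec
    epochs: dict[tuple[str, str, int], MultichannelRecording]
    coupling_by_task: dict[str, CouplingSpec]

    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.spec.n_subjects)]


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``."""
    white = rng.standard_normal(n)
    low, high = band
    nyq = fs / 2
    if low / nyq < 2e-4:
        sos = signal.butter(4, high, btype="lowpass", fs=fs, output="sos")
    else:
        sos = signal.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_coupled_recording(
    spec: CouplingSpec, rng: np.random.Generator | None = None
) -> MultichannelRecording:
    """One epoch with the planted module structure of ``spec``.

    Channel c in module g is ``mixing[c] * latent_g + noise_sd * eta_c`` with
    ``latent_g`` a shared unit-variance band-limited source and ``eta_c``
    independent white noise; ungrouped channels are pure noise.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.fs))
    mix = spec.mixing_vector()
    data = spec.noise_sd * rng.standard_normal((spec.n_channels, n_samples))
    for group in spec.groups:
        latent = _bandlimited_noise(rng, n_samples, spec.fs, spec.band)
        for ch in group:
            data[ch - 1] += mix[ch - 1] * latent
    return MultichannelRecording(data, spec.fs)


def simulate_session(spec: SessionSpec) -> Session:
    """Generate every (subject, task, stimulus) epoch of a session.

    Each epoch draws from an independent deterministic stream spawned from
    the session seed, so any single epoch is reproducible without
    regenerating the rest.
    """
    epochs: dict[tuple[str, str, int], MultichannelRecording] = {}
    coupling_by_task = {t: spec.coupling_for(t) for t in spec.tasks}
    for si in range(spec.n_subjects):
        subject = f"S{si + 1:02d}"
        for ti, task in enumerate(spec.tasks):
            cspec = coupling_by_task[task]
            for k in range(spec.stimuli_per_task):
                ss = np.random.SeedSequence(
                    entropy=spec.seed if spec.seed is not None else 0,
                    spawn_key=(si, ti, k),
                )
                rng = np.random.default_rng(ss)
                epochs[(subject, task, k)] = simulate_coupled_recording(cspec, rng)
    return Session(spec=spec, epochs=epochs, coupling_by_task=coupling_by_task)


def make_graph_fixture(kind: str, **params) -> AdjacencyMatrix:
    """Closed-form and generator graphs for metric tests.

    Kinds: ``complete``, ``path``, ``star``, ``cycle`` (param ``n``),
    ``ring_lattice`` (``n``, ``k`` nearest neighbours), ``small_world``
    (``n``, ``k``, rewiring probability ``p``, ``seed``) and ``er``
    (``n``, edge probability ``p``, ``seed``). ``star`` interprets ``n`` as
    the total node count (hub plus n-1 leaves).
    """
    n = params.get("n")
    if n is None or n < 1:
        raise ValueError("fixture needs n >= 1")
    if kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "cycle":
        g = nx.cycle_graph(n)
    elif kind == "ring_lattice":
        k = params["k"]
        if k % 2 or k >= n:
            raise ValueError("ring lattice needs even k < n")
        g = nx.watts_strogatz_graph(n, k, 0.0)
    elif kind == "small_world":
        k, p = params["k"], params["p"]
        if k % 2 or k >= n:
            raise ValueError("small-world lattice needs even k < n")
        if not 0 <= p <= 1:
            raise ValueError("rewiring probability must lie in [0, 1]")
        g = nx.watts_strogatz_graph(n, k, p, seed=params.get("seed"))
    elif kind == "er":
        p = params["p"]
        if not 0 <= p <= 1:
            raise ValueError("edge probability must lie in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=params.get("seed"))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return AdjacencyMatrix(nx.to_numpy_array(g, nodelist=range(n)))


def make_planted_feature_table(
    n_channels: int = 19,
    n_stimuli: int = 20,
    planted_groups: Sequence[Sequence[int]] = ((1, 2, 3, 4, 5, 6),
                                               (7, 8, 9, 10, 11, 12),
                                               (13, 14, 15, 16, 17, 18, 19)),
    level_offsets: Sequence[float] = (0.3, 0.2, 0.1),
    noise_sd: float = 0.02,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Channels x stimuli table with planted row groups.

    Rows in planted group g fluctuate around ``level_offsets[g]``; the
    default shape (19 x 20) mirrors one task's mean nodal-efficiency table.
    Returns ``(table, labels)`` with 0-based group labels per channel.
    """
    if len(planted_groups) != len(level_offsets):
        raise ValueError("one offset per planted group required")
    labels = np.full(n_channels, -1, dtype=int)
    for g, chans in enumerate(planted_groups):
        for ch in chans:
            if not 1 <= ch <= n_channels:
                raise ValueError(f"channel {ch} outside 1..{n_channels}")
            if labels[ch - 1] != -1:
                raise ValueError(f"channel {ch} in two planted groups")
            labels[ch - 1] = g
    if np.any(labels == -1):
        raise ValueError("planted_groups must partition all channels")
    rng = np.random.default_rng(seed)
    table = np.asarray(level_offsets, dtype=float)[labels][:, None] * np.ones(
        (1, n_stimuli)
    )
    table = table + noise_sd * rng.standard_normal((n_channels, n_stimuli))
    return table, labels


def write_session(session: Session, out_dir) -> list[Path]:
    """Persist a session: one delimited file per subject (epochs
    concatenated in task x stimulus order) plus a JSON event sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    fs = session.spec.coupling.fs
    for subject in session.subjects():
        blocks, events, t0 = [], [], 0.0
        for task in session.spec.tasks:
            for k in range(session.spec.stimuli_per_task):
                rec = session.epochs[(subject, task, k)]
                blocks.append(rec.data)
                t1 = t0 + rec.n_samples / fs
                events.append(Event(subject, task, k, t0, t1))
                t0 = t1
        rec_all = MultichannelRecording(np.concatenate(blocks, axis=1), fs)
        data_path = out_dir / f"{subject}.tsv"
        side_path = out_dir / f"{subject}.events.json"
        write_delimited(rec_all, data_path, events, side_path)
        written.extend([data_path, side_path])
    return written
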