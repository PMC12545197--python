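"""Synthetic conversational-fMRI generator.

Emulates the statistical structure the encoding analysis assumes: turn-taking
occupancy of speech production and comprehension across runs and sessions,
context-length-dependent autocorrelation of per-TR contextual embeddings,
voxels with modality-specific / shared / correlated linear tunings, FIR-lagged
hemodynamic mixing over 2-7 s delays, and AR(1) noise.

All randomness flows from a single root seed through named substreams, so a
simulation is reproducible bit-for-bit from one integer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("production", "comprehension")
#: FIR delay range in TR units (TR = 1 s).
DELAYS = tuple(range(2, 8))

# Per-run occupancy observed in natural dialogue: speakers produce speech in
# roughly half of the 430 volumes of a 7-min-10-s run and comprehend in a
# similar fraction (217.1/430 and 214.4/430 on average).
DEFAULT_OCCUPANCY = {"production": 217.1 / 430.0, "comprehension": 214.4 / 430.0}
DEFAULT_MEAN_BOUT_TR = 10.0


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a root seed (stable across runs and platforms)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class TurnParams:
    """Two-state Markov chain parameters for one modality's speech occupancy.

    ``p_enter`` is P(silent -> speaking), ``p_stay`` is P(speaking -> speaking).
    Stationary occupancy is ``p_enter / (p_enter + 1 - p_stay)`` and the mean
    speaking-bout length is ``1 / (1 - p_stay)`` TRs.
    """

    p_enter: float
    p_stay: float

    def __post_init__(self) -> None:
        for p in (self.p_enter, self.p_stay):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"transition probability {p} outside [0, 1]")

    @property
    def occupancy(self) -> float:
        denom = self.p_enter + 1.0 - self.p_stay
        return 1.0 if denom == 0 else self.p_enter / denom

    @classmethod
    def from_occupancy(cls, occupancy: float, mean_bout_tr: float = DEFAULT_MEAN_BOUT_TR) -> "TurnParams":
        if not (0.0 < occupancy < 1.0):
            raise ValueError("target occupancy must lie strictly inside (0, 1)")
        p_stay = 1.0 - 1.0 / mean_bout_tr
        p_enter = occupancy * (1.0 - p_stay) / (1.0 - occupancy)
        return cls(p_enter=min(p_enter, 1.0), p_stay=p_stay)


@dataclass
class ConversationSchedule:
    """Per-TR speech occupancy for both modalities over runs and sessions."""

    occupancy: dict[str, np.ndarray]  # modality -> bool [T]
    run_index: np.ndarray  # int [T]
    session_index: np.ndarray  # int [T]
    n_tr: int  # TRs per run (constant)

    @property
    def n_trs(self) -> int:
        return int(self.run_index.size)

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_index)

    @property
    def sessions(self) -> np.ndarray:
        return np.unique(self.session_index)

    def events_frame(self, tr_s: float = 1.0) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, text placeholder)."""
        rows = []
        for modality in MODALITIES:
            occ = self.occupancy[modality]
            for run in self.runs:
                sel = np.flatnonzero(self.run_index == run)
                flags = occ[sel]
                t = 0
                while t < flags.size:
                    if flags[t]:
                        start = t
                        while t < flags.size and flags[t]:
                            t += 1
                        rows.append(
                            {
                                "onset": start * tr_s,
                                "duration": (t - start) * tr_s,
                                "trial_type": modality,
                                "run": int(run),
                                "text": "n/a",
                            }
                        )
                    else:
                        t += 1
        return pd.DataFrame(rows).sort_values(["run", "onset", "trial_type"]).reset_index(drop=True)


def _markov_chain(rng: np.random.Generator, n: int, params: TurnParams) -> np.ndarray:
    state = rng.random() < params.occupancy
    out = np.empty(n, dtype=bool)
    u = rng.random(n)
    for t in range(n):
        out[t] = state
        p = params.p_stay if state else params.p_enter
        state = u[t] < p
    return out


def generate_schedule(
    n_sessions: int = 4,
    runs_per_session: int = 7,
    n_tr: int = 430,
    turn_params: Mapping[str, TurnParams] | None = None,
    seed: int = 0,
) -> ConversationSchedule:
    """Simulate turn-taking occupancy as independent two-state Markov chains.

    Each run restarts the chains; both modalities may co-occur in a TR
    (overlapping speech is common in free dialogue).
    """
    if n_tr < 1:
        raise ValueError("n_tr must be >= 1")
    if n_sessions < 1 or runs_per_session < 1:
        raise ValueError("n_sessions and runs_per_session must be >= 1")
    if turn_params is None:
        turn_params = {
            m: TurnParams.from_occupancy(DEFAULT_OCCUPANCY[m]) for m in MODALITIES
        }
    rng = substream(seed, "schedule")
    n_runs = n_sessions * runs_per_session
    occupancy = {m: np.empty(n_runs * n_tr, dtype=bool) for m in MODALITIES}
    run_index = np.repeat(np.arange(n_runs), n_tr)
    session_index = np.repeat(np.arange(n_runs) // runs_per_session, n_tr)
    for r in range(n_runs):
        sl = slice(r * n_tr, (r + 1) * n_tr)
        for m in MODALITIES:
            occupancy[m][sl] = _markov_chain(rng, n_tr, turn_params[m])
    return ConversationSchedule(occupancy=occupancy, run_index=run_index, session_index=session_index, n_tr=n_tr)


@dataclass
class EmbeddingStore:
    """Per-TR embedding matrices keyed by (modality, layer, context length).

    ``data[(modality, layer, context)]`` is a [T x D] matrix whose rows for
    TRs where the modality is absent are zero; ``presence[modality]`` flags
    which TRs carry content. A leading block of ``shared_dims`` coordinates
    carries a content stream common to both modalities (the shared topic of
    the conversation), gated on each modality's own presence.
    """

    data: dict[tuple[str, int, int], np.ndarray]
    presence: dict[str, np.ndarray]
    run_index: np.ndarray
    session_index: np.ndarray
    dim: int
    layers: tuple[int, ...]
    context_lengths: tuple[int, ...]
    shared_dims: int = 0

    def matrix(self, modality: str, layer: int, context: int) -> np.ndarray:
        key = (modality, int(layer), int(context))
        if key not in self.data:
            raise KeyError(f"no embeddings for modality={modality!r}, layer={layer}, context={context}")
        return self.data[key]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dim"] = self.dim
            f.attrs["shared_dims"] = self.shared_dims
            f.create_dataset("run_index", data=self.run_index)
            f.create_dataset("session_index", data=self.session_index)
            for (modality, layer, context), mat in self.data.items():
                grp = f.require_group(f"{modality}/layer{layer}/context{context}")
                grp.create_dataset("embeddings", data=mat)
            for modality, mask in self.presence.items():
                f.create_dataset(f"{modality}/presence", data=mask)

    @classmethod
    def from_hdf5(cls, path) -> "EmbeddingStore":
        import h5py

        data: dict[tuple[str, int, int], np.ndarray] = {}
        presence: dict[str, np.ndarray] = {}
        with h5py.File(path, "r") as f:
            run_index = f["run_index"][()]
            session_index = f["session_index"][()]
            dim = int(f.attrs["dim"])
            shared_dims = int(f.attrs.get("shared_dims", 0))
            for modality in f:
                if modality in ("run_index", "session_index"):
                    continue
                presence[modality] = f[f"{modality}/presence"][()].astype(bool)
                for lname in f[modality]:
                    if not lname.startswith("layer"):
                        continue
                    layer = int(lname[len("layer"):])
                    for cname in f[f"{modality}/{lname}"]:
                        context = int(cname[len("context"):])
                        data[(modality, layer, context)] = f[f"{modality}/{lname}/{cname}/embeddings"][()]
        layers = tuple(sorted({k[1] for k in data}))
        contexts = tuple(sorted({k[2] for k in data}))
        return cls(
            data=data,
            presence=presence,
            run_index=run_index,
            session_index=session_index,
            dim=dim,
            layers=layers,
            context_lengths=contexts,
            shared_dims=shared_dims,
        )


def generate_embeddings(
    schedule: ConversationSchedule,
    dim: int = 64,
    context_lengths: Sequence[int] = (1, 2, 4, 8, 16, 32),
    n_layers: int = 1,
    shared_dims: int = 0,
    topic_ar: float = 0.9,
    seed: int = 0,
) -> EmbeddingStore:
    """Draw latent per-TR content and pool it over trailing context windows.

    Each present TR gets a standard-normal latent vector; the embedding at
    context length L is the mean of the latent vectors over the trailing L
    seconds where the modality is present, mirroring token averaging over a
    growing context window. Longer windows therefore produce more
    autocorrelated features. The first ``shared_dims`` coordinates are drawn
    from a single common content stream shared by both modalities and made
    persistent by an AR(1) process with coefficient ``topic_ar`` (restarted
    per run): the topic of a conversation drifts slowly, which is what makes
    the two interlocutors' content — and hence shared explained variance —
    correlated even though they rarely speak simultaneously. Modality-unique
    coordinates are white in time.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if shared_dims < 0 or shared_dims > dim:
        raise ValueError("shared_dims must lie in [0, dim]")
    ctx = tuple(int(c) for c in context_lengths)
    if len(ctx) == 0 or any(c < 1 for c in ctx) or list(ctx) != sorted(ctx):
        raise ValueError("context lengths must be positive and sorted ascending")
    if schedule.n_trs == 0:
        raise ValueError("schedule is empty")

    if not (0.0 <= topic_ar < 1.0):
        raise ValueError("topic_ar must lie in [0, 1)")
    T = schedule.n_trs
    rng = substream(seed, "embeddings")
    data: dict[tuple[str, int, int], np.ndarray] = {}
    run_starts = {r: int(np.flatnonzero(schedule.run_index == r)[0]) for r in schedule.runs}

    for layer in range(n_layers):
        common = None
        if shared_dims:
            white = rng.standard_normal((T, shared_dims))
            common = np.empty_like(white)
            innov = np.sqrt(1.0 - topic_ar**2)
            for r in schedule.runs:
                sel = np.flatnonzero(schedule.run_index == r)
                common[sel[0]] = white[sel[0]]
                for t in sel[1:]:
                    common[t] = topic_ar * common[t - 1] + innov * white[t]
        for modality in MODALITIES:
            present = schedule.occupancy[modality]
            latent = rng.standard_normal((T, dim))
            if shared_dims:
                latent[:, :shared_dims] = common
            latent[~present] = 0.0
            for L in ctx:
                emb = np.zeros((T, dim))
                for t in np.flatnonzero(present):
                    start = max(run_starts[int(schedule.run_index[t])], t - L + 1)
                    window = np.arange(start, t + 1)
                    window = window[present[window]]
                    emb[t] = latent[window].mean(axis=0)
                data[(modality, layer, L)] = emb

    return EmbeddingStore(
        data=data,
        presence={m: schedule.occupancy[m].copy() for m in MODALITIES},
        run_index=schedule.run_index.copy(),
        session_index=schedule.session_index.copy(),
        dim=dim,
        layers=tuple(range(n_layers)),
        context_lengths=ctx,
        shared_dims=shared_dims,
    )


VOXEL_CLASSES = ("production", "comprehension", "bimodal", "cross_modal", "null")


@dataclass
class GroundTruth:
    """Per-voxel linear tunings and class labels used to synthesize BOLD.

    Classes: ``production`` / ``comprehension`` (one modality only),
    ``bimodal`` (orthogonal tunings inside the shared-content subspace, so
    both single-modality models explain the same variance), ``cross_modal``
    (tunings correlated at exactly ``rho`` across modalities) and ``null``
    (all-zero weights).
    """

    labels: np.ndarray  # str [V]
    w_production: np.ndarray  # [D x V]
    w_comprehension: np.ndarray  # [D x V]
    rho: float
    ar_coef: float
    noise_sd: float
    seed: int
    shared_dims: int = 0

    @property
    def n_voxels(self) -> int:
        return int(self.labels.size)

    @property
    def dim(self) -> int:
        return int(self.w_production.shape[0])


def _allocate_classes(class_mix: Mapping[str, float], n_voxels: int) -> np.ndarray:
    """Deterministic largest-remainder allocation of voxels to classes."""
    labels = list(class_mix)
    props = np.array([class_mix[k] for k in labels], dtype=float)
    if np.any(props < 0):
        raise ValueError("class proportions must be nonnegative")
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("class proportions must sum to 1")
    counts = np.floor(props * n_voxels).astype(int)
    remainder = n_voxels - counts.sum()
    frac = props * n_voxels - counts
    for i in np.argsort(-frac, kind="stable")[:remainder]:
        counts[i] += 1
    return np.repeat(labels, counts)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def generate_ground_truth(
    n_voxels: int = 400,
    class_mix: Mapping[str, float] | None = None,
    rho: float = 0.7,
    dim: int = 64,
    shared_dims: int = 0,
    ar_coef: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw per-voxel tuning vectors with class-dependent cross-band structure.

    Cross-modal voxels have corr(w_prod, w_comp) equal to ``rho`` exactly (the
    residual is orthogonalized before mixing). Bimodal voxels have exactly
    orthogonal tunings confined to the shared-content coordinates; unimodal
    and cross-modal tunings live in the modality-unique coordinates when a
    shared block exists.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if class_mix is None:
        class_mix = {"production": 0.2, "comprehension": 0.2, "bimodal": 0.2, "cross_modal": 0.2, "null": 0.2}
    unknown = set(class_mix) - set(VOXEL_CLASSES)
    if unknown:
        raise ValueError(f"unknown voxel classes: {sorted(unknown)}")
    labels = _allocate_classes(class_mix, n_voxels)
    rng = substream(seed, "truth")

    shared = np.arange(shared_dims)
    unique = np.arange(shared_dims, dim)
    if shared_dims and shared_dims < 2 and "bimodal" in class_mix and class_mix["bimodal"] > 0:
        raise ValueError("bimodal voxels need shared_dims >= 2 for orthogonal tunings")

    Wp = np.zeros((dim, n_voxels))
    Wc = np.zeros((dim, n_voxels))
    for v, lab in enumerate(labels):
        if lab == "null":
            continue
        if lab == "bimodal":
            idx = shared if shared_dims else np.arange(dim)
        else:
            idx = unique if shared_dims else np.arange(dim)
        a = _unit(rng.standard_normal(idx.size))
        if lab == "production":
            Wp[idx, v] = a
        elif lab == "comprehension":
            Wc[idx, v] = a
        elif lab == "bimodal":
            b = rng.standard_normal(idx.size)
            b = _unit(b - (b @ a) * a)  # exactly orthogonal tunings
            Wp[idx, v] = a
            Wc[idx, v] = b
        elif lab == "cross_modal":
            eps = rng.standard_normal(idx.size)
            # centre and orthogonalize so the *empirical* correlation is rho
            a0 = a - a.mean()
            e0 = eps - eps.mean()
            e0 = e0 - (e0 @ a0) / (a0 @ a0) * a0
            b = rho * a0 / np.linalg.norm(a0) + np.sqrt(1 - rho**2) * e0 / np.linalg.norm(e0)
            Wp[idx, v] = a0 / np.linalg.norm(a0)
            Wc[idx, v] = b
    return GroundTruth(
        labels=labels,
        w_production=Wp,
        w_comprehension=Wc,
        rho=rho,
        ar_coef=ar_coef,
        noise_sd=noise_sd,
        seed=seed,
        shared_dims=shared_dims,
    )


#: Plausible hemodynamic weighting over delays 2..7 s (peak near 4-5 s).
DEFAULT_DELAY_PROFILE = np.array([0.3, 0.8, 1.0, 0.9, 0.5, 0.2])
DEFAULT_DELAY_PROFILE = DEFAULT_DELAY_PROFILE / DEFAULT_DELAY_PROFILE.sum()


@dataclass
class BoldData:
    """BOLD matrix [T x V] with run/session row indices."""

    values: np.ndarray
    run_index: np.ndarray
    session_index: np.ndarray

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("bold", data=self.values)
            f.create_dataset("run_index", data=self.run_index)
            f.create_dataset("session_index", data=self.session_index)

    @classmethod
    def from_hdf5(cls, path) -> "BoldData":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["bold"][()], f["run_index"][()], f["session_index"][()])


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], ar: float, sd: float, run_index: np.ndarray) -> np.ndarray:
    from scipy.signal import lfilter

    white = rng.standard_normal(shape)
    if ar == 0.0:
        return sd * white
    out = np.empty(shape)
    innov_sd = np.sqrt(1.0 - ar**2)  # stationary unit marginal variance
    for r in np.unique(run_index):
        sel = run_index == r
        out[sel] = lfilter([innov_sd], [1.0, -ar], white[sel], axis=0)
    return sd * out


def simulate_bold(
    store: EmbeddingStore,
    truth: GroundTruth,
    delay_profile: np.ndarray = DEFAULT_DELAY_PROFILE,
    layer: int = 0,
    context_production: int | None = None,
    context_comprehension: int | None = None,
    seed: int = 0,
    signal_scale: float = 1.0,
) -> BoldData:
    """Mix delayed linguistic drive into voxel time series plus AR(1) noise.

    y_v(t) = signal_scale * sum_d profile[d] * x(t-d)^T w_v + AR(1) noise,
    with the FIR sum realized per run (no bleed across run boundaries) and
    absent-modality TRs contributing zero drive from that band. Each band may
    be driven at its own context length, enabling modality-specific timescale
    selectivity scenarios.
    """
    profile = np.asarray(delay_profile, dtype=float)
    if profile.shape != (len(DELAYS),):
        raise ValueError(f"delay_profile must have length {len(DELAYS)} (delays {DELAYS[0]}..{DELAYS[-1]} s)")
    if np.any(profile < 0):
        raise ValueError("delay_profile weights must be nonnegative")
    ctx_p = context_production if context_production is not None else store.context_lengths[0]
    ctx_c = context_comprehension if context_comprehension is not None else store.context_lengths[0]

    drive = (
        store.matrix("production", layer, ctx_p) @ truth.w_production
        + store.matrix("comprehension", layer, ctx_c) @ truth.w_comprehension
    )
    T, V = drive.shape
    signal = np.zeros((T, V))
    for r in np.unique(store.run_index):
        sel = np.flatnonzero(store.run_index == r)
        for w, d in zip(profile, DELAYS):
            if w == 0 or d >= sel.size:
                continue
            signal[sel[d:]] += w * drive[sel[:-d]]
    rng = substream(seed, "noise")
    noise = _ar1_noise(rng, (T, V), truth.ar_coef, truth.noise_sd, store.run_index)
    return BoldData(
        values=signal_scale * signal + noise,
        run_index=store.run_index.copy(),
        session_index=store.session_index.copy(),
    )


def oracle_noise_sd(
    store: EmbeddingStore,
    truth: GroundTruth,
    target_r: float = 0.5,
    delay_profile: np.ndarray = DEFAULT_DELAY_PROFILE,
    layer: int = 0,
    context_production: int | None = None,
    context_comprehension: int | None = None,
) -> float:
    """Noise SD giving oracle prediction accuracy ~ target_r for active voxels.

    Uses corr(signal + noise, signal) = sd_s / sqrt(sd_s^2 + sd_n^2) with the
    median signal SD over non-null voxels.
    """
    clean = GroundTruth(
        labels=truth.labels,
        w_production=truth.w_production,
        w_comprehension=truth.w_comprehension,
        rho=truth.rho,
        ar_coef=0.0,
        noise_sd=0.0,
        seed=truth.seed,
        shared_dims=truth.shared_dims,
    )
    sig = simulate_bold(
        store,
        clean,
        delay_profile=delay_profile,
        layer=layer,
        context_production=context_production,
        context_comprehension=context_comprehension,
        seed=truth.seed,
    ).values
    active = truth.labels != "null"
    sd_s = np.median(sig[:, active].std(axis=0))
    return float(sd_s * np.sqrt(1.0 / target_r**2 - 1.0))


HEAD_RADIUS_MM = 50.0


def generate_motion(
    n_tr: int,
    seed: int = 0,
    translation_step_sd_mm: float = 0.02,
    rotation_step_sd_rad: float = 2e-4,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Random-walk rigid-body motion parameters and frame-wise displacement.

    FD(t) = sum |delta translation| + 50 mm * sum |delta rotation (rad)|,
    converting rotations to arc length at an assumed 50 mm cortex-to-head-centre
    radius; FD(0) = 0 by convention.
    """
    if n_tr < 2:
        raise ValueError("n_tr must be >= 2")
    rng = substream(seed, "motion")
    steps = np.concatenate(
        [
            rng.normal(0.0, translation_step_sd_mm, size=(n_tr, 3)),
            rng.normal(0.0, rotation_step_sd_rad, size=(n_tr, 3)),
        ],
        axis=1,
    )
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    table = pd.DataFrame(params, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"])
    return table, framewise_displacement(table)


def framewise_displacement(params: pd.DataFrame) -> np.ndarray:
    """FD from a six-column motion table (3 translations mm, 3 rotations rad)."""
    arr = params[["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]].to_numpy(dtype=float)
    d = np.abs(np.diff(arr, axis=0))
    fd = d[:, :3].sum(axis=1) + HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])
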