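"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one of the experiment's data modalities:

* :func:`simulate_counts` — hybridization-counter miRNA count matrices with
  control probes, per-sample spike-in scale factors, negative-binomial
  counting noise and condition-specific planted fold changes;
* :func:`simulate_recording` — extracellular voltage traces: Gaussian noise
  plus ~1 ms biphasic spike waveforms at known times, with Poisson background
  spiking and inserted bursts;
* :func:`simulate_ct` — qRT-PCR Ct tables with planted fold changes encoded
  as -log2(FC) cycle shifts against a stable housekeeping target;
* :func:`simulate_utr` — random 3'-UTR sequences carrying exact planted seed
  sites and screened so no accidental site of the planted miRNAs survives.

All generators are seeded and deterministic, and every truth object checks
its own invariants before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import CtTable, MiRNACountMatrix
from .mea import ElectrodeRecording
from .seedscan import SeedSite, _TRANSVERSION, _revcomp, clean_sequence, seed_sites

__all__ = [
    "CountSimTruth",
    "TraceSimTruth",
    "default_mirna_ids",
    "abundance_profile",
    "simulate_counts",
    "plan_spikes",
    "scale_activity",
    "simulate_recording",
    "simulate_ct",
    "simulate_utr",
    "POSITIVE_CONTROL_MEANS",
    "NEGATIVE_CONTROL_MEAN",
]

# spike-in ladder (counts at unit technical factor) and background level,
# loosely following the geometric positive-control ladder of nCounter panels
POSITIVE_CONTROL_MEANS = {
    "POS_A": 16384.0,
    "POS_B": 4096.0,
    "POS_C": 1024.0,
    "POS_D": 256.0,
    "POS_E": 64.0,
    "POS_F": 16.0,
}
NEGATIVE_CONTROL_MEAN = 12.0
N_NEGATIVE_CONTROLS = 8


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountSimTruth:
    """Ground truth for a simulated count matrix.

    ``enriched_map`` maps condition -> {miRNA id: planted fold change};
    ``baseline_mean`` is the expected endogenous count in the baseline
    condition — a scalar applied to every miRNA, or a per-miRNA mapping
    (realistic abundances span orders of magnitude; see
    :func:`abundance_profile`); ``dispersion`` is the negative-binomial
    dispersion (variance = mean + dispersion * mean^2; zero degenerates to
    deterministic means); ``spikein_factors`` maps sample id ->
    multiplicative technical factor.
    """

    enriched_map: dict[str, dict[str, float]]
    baseline_mean: float | dict[str, float] = 500.0
    dispersion: float = 0.05
    spikein_factors: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for cond, fcs in self.enriched_map.items():
            for mirna, fc in fcs.items():
                if fc <= 0:
                    raise ValueError(f"planted fold change for {mirna!r} must be > 0")
        if isinstance(self.baseline_mean, Mapping):
            if any(v <= 0 for v in self.baseline_mean.values()):
                raise ValueError("baseline_mean values must be positive")
        elif self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for s, f in self.spikein_factors.items():
            if f <= 0:
                raise ValueError(f"spike-in factor for sample {s!r} must be > 0")

    def planted(self, condition: str) -> set[str]:
        return set(self.enriched_map.get(condition, {}))


def default_mirna_ids(n_mirnas: int, planted_ids: Sequence[str] = ()) -> list[str]:
    """Panel probe ids: the planted ids first, then ``miR-NNN`` fill."""
    ids = list(dict.fromkeys(planted_ids))
    if n_mirnas < len(ids):
        raise ValueError("n_mirnas must be >= number of planted enriched miRNAs")
    i = 1
    while len(ids) < n_mirnas:
        candidate = f"miR-{i:03d}"
        if candidate not in ids:
            ids.append(candidate)
        i += 1
    return ids


def abundance_profile(
    mirna_ids: Sequence[str],
    planted_ids: Sequence[str] = (),
    seed: int = 0,
    background_range: tuple[float, float] = (50.0, 20000.0),
    planted_range: tuple[float, float] = (100.0, 5000.0),
) -> dict[str, float]:
    """Per-miRNA baseline means, log-uniform over a realistic dynamic range.

    Planted (enriched) miRNAs are drawn from a mid-abundance band so that a
    doubled count still has rank headroom below the most abundant probes —
    quantile normalization cannot represent enrichment of a probe that is
    already rank-maximal (see the methods note).
    """
    rng = np.random.default_rng(seed)
    planted = set(planted_ids)
    out: dict[str, float] = {}
    for mid in mirna_ids:
        lo, hi = planted_range if mid in planted else background_range
        out[mid] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with var = mean + dispersion*mean^2; dispersion 0
    returns the mean exactly (noise-free)."""
    mean = np.asarray(mean, float)
    if dispersion == 0:
        return mean.copy()
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    return rng.negative_binomial(n, p, size=mean.shape).astype(float)


def simulate_counts(
    n_mirnas: int,
    conditions: Mapping[str, int] | Sequence[str],
    truth: CountSimTruth,
    baseline: str | None = None,
) -> tuple[MiRNACountMatrix, CountSimTruth]:
    """Simulate a raw probe x sample count matrix with planted enrichment.

    ``conditions`` maps condition label -> number of replicate samples (a
    plain sequence of labels means one sample each).  Endogenous miRNA ids
    are ``miR-001`` .. ``miR-NNN`` unless the planted map names other ids, in
    which case those ids must be resolvable among the generated ones (the
    planted ids replace the first generated ids).  Endogenous counts are
    NB(baseline_mean x planted FC x spike-in factor, dispersion);
    positive-control probes scale only with the spike-in factor;
    negative-control probes sit at a low fixed mean.
    """
    truth.validate()
    if isinstance(conditions, Mapping):
        cond_reps = dict(conditions)
    else:
        cond_reps = {c: 1 for c in conditions}
    planted_ids: list[str] = []
    for fcs in truth.enriched_map.values():
        for mid in fcs:
            if mid not in planted_ids:
                planted_ids.append(mid)
    mirna_ids = default_mirna_ids(n_mirnas, planted_ids)
    for cond, fcs in truth.enriched_map.items():
        if cond not in cond_reps:
            raise ValueError(f"planted condition {cond!r} not among the sample conditions")
        for mid in fcs:
            if mid not in mirna_ids:
                raise ValueError(f"planted miRNA {mid!r} not in the matrix")

    samples: list[str] = []
    cond_of: dict[str, str] = {}
    for cond, reps in cond_reps.items():
        for r in range(1, reps + 1):
            sid = f"{cond}_r{r:02d}"
            samples.append(sid)
            cond_of[sid] = cond
    factors = {s: truth.spikein_factors.get(s, 1.0) for s in samples}
    truth = replace(truth, spikein_factors=factors)
    truth.validate()

    rng = np.random.default_rng(truth.seed)
    probe_ids = mirna_ids + list(POSITIVE_CONTROL_MEANS) + [
        f"NEG_{chr(ord('A') + i)}" for i in range(N_NEGATIVE_CONTROLS)
    ]
    classes = (
        ["endogenous"] * len(mirna_ids)
        + ["positive"] * len(POSITIVE_CONTROL_MEANS)
        + ["negative"] * N_NEGATIVE_CONTROLS
    )
    if isinstance(truth.baseline_mean, Mapping):
        missing = [m for m in mirna_ids if m not in truth.baseline_mean]
        if missing:
            raise ValueError(f"baseline_mean mapping lacks miRNAs: {missing[:5]}")
        base_means = np.array([truth.baseline_mean[m] for m in mirna_ids])
    else:
        base_means = np.full(len(mirna_ids), float(truth.baseline_mean))

    cols = {}
    pos_means = np.array(list(POSITIVE_CONTROL_MEANS.values()))
    neg_means = np.full(N_NEGATIVE_CONTROLS, NEGATIVE_CONTROL_MEAN)
    for s in samples:
        cond = cond_of[s]
        fc = np.array(
            [truth.enriched_map.get(cond, {}).get(mid, 1.0) for mid in mirna_ids]
        )
        endo_mean = base_means * fc * factors[s]
        col = np.concatenate(
            [
                _nb_draw(rng, endo_mean, truth.dispersion),
                _nb_draw(rng, pos_means * factors[s], truth.dispersion),
                _nb_draw(rng, neg_means, truth.dispersion),
            ]
        )
        cols[s] = col
    values = pd.DataFrame(cols, index=probe_ids)
    matrix = MiRNACountMatrix(
        values=values,
        probe_class=pd.Series(classes, index=probe_ids),
        conditions=pd.Series(cond_of),
        state="raw",
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# voltage traces


@dataclass
class TraceSimTruth:
    """Ground truth for simulated extracellular recordings.

    ``true_spike_times`` / ``true_burst_windows`` are per-electrode; the
    spike amplitude is the absolute waveform peak expressed as a multiple of
    the noise SD.
    """

    true_spike_times: dict[str, np.ndarray]
    true_burst_windows: dict[str, list[tuple[float, float]]]
    noise_sd: float = 5.0  # uV
    spike_amplitude: float = 10.0  # x noise SD, absolute peak
    sampling_rate: float = 25000.0  # Hz
    seed: int = 0

    def validate(self, duration: float | None = None) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spike_amplitude < 0:
            raise ValueError("spike_amplitude must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for eid, t in self.true_spike_times.items():
            t = np.asarray(t)
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"spike times for {eid!r} must be sorted")
            if t.size and (t.min() < 0 or (duration is not None and t.max() > duration)):
                raise ValueError(f"spike times for {eid!r} outside [0, duration]")
        for eid, wins in self.true_burst_windows.items():
            t = np.asarray(self.true_spike_times.get(eid, np.empty(0)))
            for (a, b) in wins:
                inside = t[(t >= a) & (t <= b)]
                if inside.size < 4 or (inside.size > 1 and np.any(np.diff(inside) > 0.1)):
                    raise ValueError(
                        f"burst window ({a}, {b}) on {eid!r} violates the >=4 spikes "
                        "/ <=0.1 s gap invariant"
                    )


def plan_spikes(
    duration: float,
    electrodes: int | Sequence[str],
    *,
    background_rate: float = 2.0,  # spikes/s
    burst_rate: float = 10.0,  # bursts/min
    noise_sd: float = 5.0,
    spike_amplitude: float = 10.0,
    sampling_rate: float = 25000.0,
    dead_time: float = 0.001,
    min_burst_gap: float = 0.5,
    seed: int = 0,
) -> TraceSimTruth:
    """Draw ground-truth spike times and burst windows for each electrode.

    Background spikes are homogeneous Poisson; bursts are inserted as
    clusters of 4-8 spikes with intra-burst inter-spike intervals drawn
    uniformly from [20, 50] ms, separated by at least ``min_burst_gap``
    seconds of quiescence so distinct bursts stay distinct under the
    100 ms chaining rule.  After merging, spikes closer than ``dead_time``
    (the detector's refractory window) are dropped from truth.
    """
    if isinstance(electrodes, int):
        electrode_ids = [f"el{i:02d}" for i in range(1, electrodes + 1)]
    else:
        electrode_ids = list(electrodes)
    rng = np.random.default_rng(seed)
    spike_times: dict[str, np.ndarray] = {}
    burst_windows: dict[str, list[tuple[float, float]]] = {}
    margin = 0.002  # keep waveforms fully inside the trace
    for eid in electrode_ids:
        n_bg = rng.poisson(background_rate * duration)
        bg = rng.uniform(margin, duration - margin, size=n_bg)
        burst_spikes: list[float] = []
        windows: list[tuple[float, float]] = []
        n_bursts = rng.poisson(burst_rate * duration / 60.0)
        for _ in range(n_bursts):
            n_sp = int(rng.integers(4, 9))
            isis = rng.uniform(0.020, 0.050, size=n_sp - 1)
            span = float(isis.sum())
            start = None
            for _attempt in range(100):
                cand = rng.uniform(margin, max(duration - margin - span, margin))
                conflict = any(
                    cand - min_burst_gap < b and a < cand + span + min_burst_gap
                    for (a, b) in windows
                )
                if not conflict:
                    start = cand
                    break
            if start is None:
                continue  # no room left for a separated burst
            times = start + np.concatenate([[0.0], np.cumsum(isis)])
            times = times[times < duration - margin]
            if times.size >= 4:
                burst_spikes.extend(times)
                windows.append((float(times[0]), float(times[-1])))
        merged = np.sort(np.concatenate([bg, np.asarray(burst_spikes)]))
        # drop collisions closer than the detector dead time
        keep = []
        last = -np.inf
        for t in merged:
            if t - last >= dead_time:
                keep.append(t)
                last = t
        spike_times[eid] = np.asarray(keep)
        # re-validate burst windows after collision dropping
        windows = [
            w
            for w in windows
            if _window_still_bursts(spike_times[eid], w)
        ]
        burst_windows[eid] = sorted(windows)
    truth = TraceSimTruth(
        true_spike_times=spike_times,
        true_burst_windows=burst_windows,
        noise_sd=noise_sd,
        spike_amplitude=spike_amplitude,
        sampling_rate=sampling_rate,
        seed=seed,
    )
    truth.validate(duration)
    return truth


def _window_still_bursts(times: np.ndarray, window: tuple[float, float]) -> bool:
    inside = times[(times >= window[0]) & (times <= window[1])]
    return inside.size >= 4 and (inside.size < 2 or not np.any(np.diff(inside) > 0.1))


def scale_activity(
    truth: TraceSimTruth,
    duration: float,
    spike_scale: float,
    burst_scale: float,
    seed: int,
    *,
    min_burst_gap: float = 0.5,
    dead_time: float = 0.001,
) -> TraceSimTruth:
    """Derive a treatment epoch from a baseline truth by scaling activity.

    Spike and burst counts are moved to ``scale`` x baseline per electrode:
    scales <= 1 thin bursts/spikes (count-deterministic), scales > 1 insert
    additional bursts (in quiescent gaps) and background spikes.  Burst
    windows are re-validated after merging.
    """
    if spike_scale < 0 or burst_scale < 0:
        raise ValueError("scales must be nonnegative")
    rng = np.random.default_rng(seed)
    margin = 0.002
    new_spikes: dict[str, np.ndarray] = {}
    new_windows: dict[str, list[tuple[float, float]]] = {}
    for eid, times in truth.true_spike_times.items():
        wins = list(truth.true_burst_windows.get(eid, []))
        in_burst = np.zeros(times.size, dtype=bool)
        for (a, b) in wins:
            in_burst |= (times >= a) & (times <= b)
        lone = times[~in_burst]
        extra_burst_spikes: list[float] = []
        if burst_scale <= 1.0:
            n_keep = int(round(burst_scale * len(wins)))
            idx = rng.choice(len(wins), size=n_keep, replace=False) if wins else []
            keep_wins = [wins[i] for i in sorted(idx)]
        else:
            keep_wins = list(wins)
            n_extra = int(round((burst_scale - 1.0) * len(wins)))
            for _ in range(n_extra):
                n_sp = int(rng.integers(4, 9))
                isis = rng.uniform(0.020, 0.050, size=n_sp - 1)
                span = float(isis.sum())
                for _attempt in range(200):
                    cand = rng.uniform(margin, max(duration - margin - span, margin))
                    if not any(
                        cand - min_burst_gap < b and a < cand + span + min_burst_gap
                        for (a, b) in keep_wins
                    ):
                        t_new = cand + np.concatenate([[0.0], np.cumsum(isis)])
                        extra_burst_spikes.extend(t_new)
                        keep_wins.append((float(t_new[0]), float(t_new[-1])))
                        break
        kept_burst = np.zeros(times.size, dtype=bool)
        for (a, b) in keep_wins:
            kept_burst |= (times >= a) & (times <= b)
        n_burst_spikes = int(kept_burst.sum()) + len(extra_burst_spikes)
        target_total = int(round(spike_scale * times.size))
        n_lone = max(target_total - n_burst_spikes, 0)
        if n_lone <= lone.size:
            idx = rng.choice(lone.size, size=n_lone, replace=False) if lone.size else []
            lone_kept = lone[np.sort(idx)]
            extra_lone = np.empty(0)
        else:
            lone_kept = lone
            extra_lone = rng.uniform(margin, duration - margin, size=n_lone - lone.size)
        merged = np.sort(
            np.concatenate([times[kept_burst], np.asarray(extra_burst_spikes),
                            lone_kept, extra_lone])
        )
        keep: list[float] = []
        last = -np.inf
        for t in merged:
            if t - last >= dead_time:
                keep.append(t)
                last = t
        new_spikes[eid] = np.asarray(keep)
        new_windows[eid] = sorted(
            w for w in keep_wins if _window_still_bursts(new_spikes[eid], w)
        )
    out = TraceSimTruth(
        true_spike_times=new_spikes,
        true_burst_windows=new_windows,
        noise_sd=truth.noise_sd,
        spike_amplitude=truth.spike_amplitude,
        sampling_rate=truth.sampling_rate,
        seed=int(rng.integers(0, 2**31)),
    )
    out.validate(duration)
    return out


def _biphasic_waveform(sampling_rate: float, amplitude: float, width: float = 0.001) -> np.ndarray:
    """~1 ms biphasic (negative-then-positive) template with absolute peak
    ``amplitude``; one full sine cycle over the width."""
    n = max(int(round(width * sampling_rate)), 2)
    t = np.arange(n) / n
    return -amplitude * np.sin(2.0 * np.pi * t)


def simulate_recording(
    duration: float,
    electrodes: int | Sequence[str] | None,
    truth: TraceSimTruth,
    epoch: str = "pre",
) -> tuple[list[ElectrodeRecording], TraceSimTruth]:
    """Render voltage traces from a spike-time truth object.

    Each trace is Gaussian noise (SD ``truth.noise_sd``) plus the biphasic
    waveform added at every true spike time.  ``electrodes`` may restrict /
    order the rendered electrode ids (None renders all in the truth).
    """
    if truth.sampling_rate < 10_000:
        raise ValueError("sampling_rate must be >= 10 kHz for spike-resolved traces")
    truth.validate(duration)
    if electrodes is None:
        electrode_ids = list(truth.true_spike_times)
    elif isinstance(electrodes, int):
        electrode_ids = list(truth.true_spike_times)[:electrodes]
    else:
        electrode_ids = list(electrodes)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0xE1EC]))
    n_samples = int(round(duration * truth.sampling_rate))
    amp = truth.spike_amplitude * truth.noise_sd
    wave = _biphasic_waveform(truth.sampling_rate, amp)
    recs = []
    for eid in electrode_ids:
        times = np.asarray(truth.true_spike_times.get(eid, np.empty(0)))
        if times.size and times.max() > duration:
            raise ValueError(f"spike times beyond duration on electrode {eid!r}")
        x = rng.normal(0.0, truth.noise_sd, size=n_samples)
        for t in times:
            i = int(round(t * truth.sampling_rate))
            j = min(i + wave.size, n_samples)
            x[i:j] += wave[: j - i]
        recs.append(
            ElectrodeRecording(
                electrode_id=eid,
                sampling_rate=truth.sampling_rate,
                samples=x,
                epoch=epoch,
            )
        )
    return recs, truth


# ---------------------------------------------------------------------------
# qRT-PCR


def simulate_ct(
    targets: Sequence[str],
    planted_fc: Mapping[str, float],
    hk_id: str,
    seed: int = 0,
    *,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    hk_ct: float = 20.0,
) -> tuple[CtTable, dict[str, float]]:
    """Simulate a Ct table in which the treated group carries each target's
    planted fold change as a -log2(FC) cycle shift.

    Returns the table and the planted-FC map (the truth).  The housekeeping
    target is constant (up to noise) in both groups.
    """
    if not hk_id:
        raise ValueError("housekeeping id missing")
    for t, fc in planted_fc.items():
        if fc <= 0:
            raise ValueError(f"planted fold change for {t!r} must be > 0")
        if t not in targets:
            raise ValueError(f"planted target {t!r} not among targets")
    rng = np.random.default_rng(seed)
    base_ct = {t: float(rng.uniform(22.0, 28.0)) for t in targets}
    rows = []
    for group in ("calibrator", "treated"):
        for r in range(1, n_replicates + 1):
            sample = f"{group}_{r:02d}"
            for t in targets:
                shift = -np.log2(planted_fc.get(t, 1.0)) if group == "treated" else 0.0
                ct = base_ct[t] + shift + rng.normal(0.0, noise_sd)
                rows.append({"sample": sample, "group": group, "target": t, "ct": ct})
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "target": hk_id,
                    "ct": hk_ct + rng.normal(0.0, noise_sd),
                }
            )
    table = CtTable(data=pd.DataFrame(rows), housekeeping=hk_id)
    return table, dict(planted_fc)


# ---------------------------------------------------------------------------
# UTRs


_SITE_BUILDERS = {
    "6mer": lambda m: _revcomp(m[1:7]),
    "7mer-A1": lambda m: _revcomp(m[1:7]) + "A",
    "7mer-m8": lambda m: _revcomp(m[1:8]),
    "8mer": lambda m: _revcomp(m[1:8]) + "A",
}


def simulate_utr(
    length: int,
    planted: Sequence[tuple[str, int, str]],
    seed: int = 0,
    *,
    screen_mirnas: Sequence[str] = (),
    max_patch_rounds: int = 200,
) -> tuple[str, list[SeedSite]]:
    """Random UTR sequence with exact planted seed sites and no accidental
    sites for the planted (or ``screen_mirnas``) miRNAs anywhere else.

    ``planted`` is a list of (mature miRNA sequence, start position, site
    type).  The background is patched (single-base transversions outside the
    planted footprints) until a scan of every planted miRNA reports exactly
    the planted sites; miRNAs listed in ``screen_mirnas`` must end up with no
    site at all (negative controls by construction).
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    footprints: list[tuple[int, int]] = []
    truth: list[SeedSite] = []
    mirnas: list[str] = []
    for mseq, pos, site_type in planted:
        if site_type not in _SITE_BUILDERS:
            raise ValueError(f"unknown site type {site_type!r}")
        m = clean_sequence(mseq, "miRNA")
        if len(m) < 8:
            raise ValueError("mature miRNA must be at least 8 nt")
        site_str = _SITE_BUILDERS[site_type](m)
        end = pos + len(site_str)
        if pos < 0 or end > length:
            raise ValueError(f"planted site at {pos} extends beyond the UTR")
        for (a, b) in footprints:
            if pos < b and a < end:
                raise ValueError("overlapping planted sites")
        footprints.append((pos, end))
        truth.append(SeedSite("utr", pos, end, site_type, f"planted_{len(truth)}"))
        mirnas.append(m)
        seq[pos:end] = list(site_str)

    def protected(i: int) -> bool:
        return any(a <= i < b for a, b in footprints)

    # allowed (start, end, type) per miRNA sequence; screened miRNAs allow none
    allowed: dict[str, set[tuple[int, int, str]]] = {}
    for m, want in zip(mirnas, truth):
        allowed.setdefault(m, set()).add((want.start, want.end, want.site_type))
    for extra in screen_mirnas:
        allowed.setdefault(clean_sequence(extra, "miRNA"), set())
    scan_plan = list(allowed.items())

    # guard the flanks of sub-8mer planted sites so they scan as the planted
    # type, then remove accidental sites elsewhere
    for _ in range(max_patch_rounds):
        s = "".join(seq)
        offending: list[int] = []
        for m, ok_sites in scan_plan:
            for hit in seed_sites(s, m):
                if (hit.start, hit.end, hit.site_type) in ok_sites:
                    continue
                span = range(hit.start, hit.end)
                free = [i for i in span if not protected(i)]
                if not free:
                    raise ValueError("cannot patch a site overlapping only planted bases")
                # prefer a core base so one transversion kills the match
                c0, c1 = (hit.start + 1, hit.start + 7) if hit.site_type in (
                    "8mer", "7mer-m8") else (hit.start, hit.start + 6)
                core_free = [i for i in free if c0 <= i < c1]
                offending.append((core_free or free)[0])
        if not offending:
            break
        for i in set(offending):
            seq[i] = _TRANSVERSION[seq[i]]
    else:
        raise RuntimeError("background screening did not converge")
    return "".join(seq), truth
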