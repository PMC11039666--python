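"""Temporal classification and wave clustering of super-enhancers.

Across a two-arm treatment time course (vehicle control vs inducer at
days 2/4/8), per-sample SE calls are merged into a master SE set, each
master SE is quantified as RPM over every sample, and the set is
partitioned:

* stable SEs -- coefficient of variation of the RPM over the treated time
  course (control baseline included) below a threshold (default 30%);
* condition-invariant SEs -- the remaining SEs whose day-matched
  treated-vs-control RPM difference never reaches a threshold (default
  200 RPM), i.e. whatever change they show is time-driven rather than
  treatment-specific;
* dynamic SEs -- everything else.  Dynamic SEs are z-scored over the
  ordered time axis and K-means clustered; clusters are labelled by the
  position of their centroid maximum: baseline -> "lost", day 2/4/8 ->
  "wave_2d"/"wave_4d"/"wave_8d".  Clusters sharing an argmax position are
  merged under one label, so k = 5 can still report four waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .io_formats import CoverageMap, GenomicInterval
from .se_calling import rpm_normalize

WAVE_LABELS = ("lost", "wave_2d", "wave_4d", "wave_8d")


@dataclass
class SETemporalProfile:
    """Per-master-SE signal over samples with its class and wave labels."""

    se_id: str
    interval: GenomicInterval
    signal: dict[str, float]
    zscores: dict[str, float] = field(default_factory=dict)
    class_label: str = ""  # stable | condition_invariant | dynamic
    wave_label: str = "none"  # lost | wave_2d | wave_4d | wave_8d | none


@dataclass
class WaveConfig:
    """Thresholds and sample roles for the temporal partition.

    ``baseline_sample`` is the control-arm reference entering the treated
    time axis; ``atra_samples``/``control_samples`` are the day-ordered
    treated and control samples (day-matched, equal length).
    """

    stable_cv_max: float = 0.30
    invariance_threshold: float = 200.0
    k: int = 5
    n_init: int = 25
    seed: int = 0
    baseline_sample: str = "EtOH_2D"
    atra_samples: tuple[str, ...] = ("ATRA_2D", "ATRA_4D", "ATRA_8D")
    control_samples: tuple[str, ...] = ("EtOH_2D", "EtOH_4D", "EtOH_8D")
    elbow_range: tuple[int, int] = (2, 8)

    def __post_init__(self) -> None:
        if not (0 < self.stable_cv_max < 1):
            raise ValueError("stable_cv_max must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if len(self.atra_samples) != len(self.control_samples):
            raise ValueError("atra_samples and control_samples must be day-matched")

    @property
    def zscore_samples(self) -> tuple[str, ...]:
        """Ordered time axis for z-scoring: baseline then treated days."""
        return (self.baseline_sample, *self.atra_samples)


# ---------------------------------------------------------------------------
# Master set
# ---------------------------------------------------------------------------


def build_master_set(
    se_sets: dict[str, list[GenomicInterval]],
    min_overlap_frac: float = 0.5,
) -> tuple[list[tuple[str, GenomicInterval]], dict[str, dict[str, list[GenomicInterval]]]]:
    """Merge per-sample SE calls into a master SE set.

    Master intervals are the any-overlap merge of the concatenated calls.
    The membership map records, per master SE and sample, the sample SEs
    that overlap it by at least ``min_overlap_frac`` of the smaller
    interval.  Returns ([(se_id, interval), ...], membership).
    """
    if not se_sets:
        raise ValueError("need at least one SE set")
    tagged = [
        (iv, sample) for sample, ivs in se_sets.items() for iv in ivs
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))

    merged: list[tuple[GenomicInterval, list[tuple[GenomicInterval, str]]]] = []
    for iv, sample in tagged:
        if merged and merged[-1][0].chrom == iv.chrom and iv.start < merged[-1][0].end:
            cur, members = merged.pop()
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end))
            members.append((iv, sample))
            merged.append((cur, members))
        else:
            merged.append((iv, [(iv, sample)]))

    width = max(4, len(str(len(merged))))
    master: list[tuple[str, GenomicInterval]] = []
    membership: dict[str, dict[str, list[GenomicInterval]]] = {}
    for i, (iv, members) in enumerate(merged, start=1):
        se_id = f"mse_{i:0{width}d}"
        master.append((se_id, iv))
        by_sample: dict[str, list[GenomicInterval]] = {}
        for member_iv, sample in members:
            smaller = min(member_iv.length, iv.length)
            if member_iv.overlap_length(iv) >= min_overlap_frac * smaller:
                by_sample.setdefault(sample, []).append(member_iv)
        membership[se_id] = by_sample
    return master, membership


def quantify_profiles(
    master: list[tuple[str, GenomicInterval]],
    coverage: dict[str, CoverageMap],
    totals: dict[str, float],
) -> pd.DataFrame:
    """RPM profile matrix (master SE x sample): coverage sum over the
    master interval, normalized per million mapped reads."""
    missing = set(coverage) ^ set(totals)
    if missing:
        raise ValueError(f"samples missing coverage or totals: {sorted(missing)}")
    data = {
        sample: [
            float(rpm_normalize(coverage[sample].query(iv), totals[sample]))
            for _, iv in master
        ]
        for sample in coverage
    }
    return pd.DataFrame(data, index=[se_id for se_id, _ in master])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def classify_stable(atras: np.ndarray, cv_max: float = 0.30) -> bool:
    """True when the sample-SD / mean (CV) over the treated time course is
    below ``cv_max``.  A flat zero vector counts as stable."""
    v = np.asarray(atras, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 time points")
    mean = v.mean()
    if mean == 0:
        return True
    return float(v.std(ddof=1)) / mean < cv_max


def classify_condition_invariant(
    atra: np.ndarray, control: np.ndarray, threshold: float = 200.0
) -> bool:
    """True when the largest day-matched |treated - control| difference is
    below ``threshold`` RPM (the change is time-driven, not treatment
    specific)."""
    a = np.asarray(atra, dtype=float)
    c = np.asarray(control, dtype=float)
    if a.shape != c.shape:
        raise ValueError("day-matched vectors must have equal length")
    return float(np.abs(a - c).max()) < threshold


def zscore_profile(values: np.ndarray) -> np.ndarray:
    """(v - mean) / population SD; a constant vector maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_waves(
    zmatrix: pd.DataFrame, cfg: WaveConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """K-means (Lloyd, k-means++ init, ``n_init`` restarts) on the z-score
    matrix; also computes a WCSS elbow table over ``cfg.elbow_range``.

    Returns (labels, centroids, elbow table); fully reproducible for a
    fixed ``cfg.seed``.
    """
    X = zmatrix.to_numpy(dtype=float)
    if X.shape[0] < cfg.k:
        raise ValueError(f"need at least k={cfg.k} rows, got {X.shape[0]}")
    with warnings.catch_warnings():
        # duplicate rows are expected in the noiseless limit
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(
            n_clusters=cfg.k,
            n_init=cfg.n_init,
            random_state=cfg.seed,
            algorithm="lloyd",
        ).fit(X)
        lo, hi = cfg.elbow_range
        elbow_rows = []
        for k in range(lo, min(hi, X.shape[0]) + 1):
            wcss = KMeans(
                n_clusters=k, n_init=cfg.n_init, random_state=cfg.seed, algorithm="lloyd"
            ).fit(X).inertia_
            elbow_rows.append({"k": k, "wcss": float(wcss)})
    elbow = pd.DataFrame(elbow_rows)
    return km.labels_, km.cluster_centers_, elbow


def label_waves(
    centroids: np.ndarray,
    time_order: tuple[str, ...] = ("baseline", "2D", "4D", "8D"),
) -> dict[int, str]:
    """Map each centroid to a wave label by its argmax on the time axis.

    baseline-peaked -> "lost"; day-2/4/8-peaked -> "wave_2d"/"wave_4d"/
    "wave_8d".  Centroids sharing an argmax position merge under the same
    label (so k = 5 can report four waves).
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[1] != len(time_order):
        raise ValueError("centroid width must match the time axis")
    wave_by_pos = dict(zip(range(len(time_order)), WAVE_LABELS))
    return {
        ci: wave_by_pos[int(np.argmax(centroids[ci]))]
        for ci in range(centroids.shape[0])
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def classify_profiles(profiles: pd.DataFrame, cfg: WaveConfig) -> pd.DataFrame:
    """Partition master SEs into stable / condition-invariant / dynamic and
    wave-cluster the dynamic ones.

    Filter order: the stable filter runs first, the invariance filter on
    the survivors, and clustering on the remainder only.  Returns a table
    indexed by se_id with class_label, wave_label, cv, max_cond_diff,
    cluster and the z-scores over the ordered time axis.
    """
    needed = set(cfg.zscore_samples) | set(cfg.control_samples)
    missing = needed - set(profiles.columns)
    if missing:
        raise ValueError(f"profile matrix missing samples: {sorted(missing)}")

    atra_axis = profiles[list(cfg.zscore_samples)].to_numpy(dtype=float)
    atra_days = profiles[list(cfg.atra_samples)].to_numpy(dtype=float)
    ctrl_days = profiles[list(cfg.control_samples)].to_numpy(dtype=float)

    n = len(profiles)
    cv = np.full(n, np.nan)
    means = atra_axis.mean(axis=1)
    sds = atra_axis.std(axis=1, ddof=1)
    nonzero = means > 0
    cv[nonzero] = sds[nonzero] / means[nonzero]
    stable = np.where(nonzero, cv < cfg.stable_cv_max, True)

    max_diff = np.abs(atra_days - ctrl_days).max(axis=1)
    invariant = (~stable) & (max_diff < cfg.invariance_threshold)
    dynamic = ~stable & ~invariant

    out = pd.DataFrame(
        {
            "class_label": np.where(
                stable, "stable", np.where(invariant, "condition_invariant", "dynamic")
            ),
            "wave_label": "none",
            "cv": cv,
            "max_cond_diff": max_diff,
            "cluster": -1,
        },
        index=profiles.index,
    )

    zcols = [f"z_{s}" for s in cfg.zscore_samples]
    zmat = np.vstack([zscore_profile(row) for row in atra_axis]) if n else np.empty((0, len(zcols)))
    for j, col in enumerate(zcols):
        out[col] = zmat[:, j] if n else []

    dyn_idx = profiles.index[dynamic]
    if len(dyn_idx) >= cfg.k:
        zdf = pd.DataFrame(zmat[dynamic], index=dyn_idx, columns=zcols)
        labels, centroids, elbow = cluster_waves(zdf, cfg)
        wave_map = label_waves(centroids)
        out.loc[dyn_idx, "cluster"] = labels
        out.loc[dyn_idx, "wave_label"] = [wave_map[int(l)] for l in labels]
        out.attrs["centroids"] = centroids
        out.attrs["elbow"] = elbow
        out.attrs["wave_map"] = wave_map
    elif len(dyn_idx):
        raise ValueError(
            f"{len(dyn_idx)} dynamic SEs but k={cfg.k}; lower k or add data"
        )
    return out


def partition_summary(classification: pd.DataFrame) -> dict[str, int]:
    """Count table for the partition; enforces the partition identity
    (stable + invariant + dynamic = total, wave counts sum to dynamic)."""
    if (classification["class_label"] == "").any():
        raise ValueError("unclassified SEs present")
    cls = classification["class_label"]
    counts = {
        "n_total": int(len(classification)),
        "n_stable": int((cls == "stable").sum()),
        "n_invariant": int((cls == "condition_invariant").sum()),
        "n_dynamic": int((cls == "dynamic").sum()),
    }
    for wave in WAVE_LABELS:
        counts[f"n_{wave}"] = int((classification["wave_label"] == wave).sum())
    assert counts["n_stable"] + counts["n_invariant"] + counts["n_dynamic"] == counts["n_total"]
    assert sum(counts[f"n_{w}"] for w in WAVE_LABELS) == counts["n_dynamic"]
    return counts
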