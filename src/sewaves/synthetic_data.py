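"""Synthetic input bundles with known ground truth.

The generator emulates the data layout of an H3K27ac ChIP-seq time course
over two arms (vehicle control "EtOH" and inducer "ATRA", days 2/4/8, one
ChIP sample per time point): per-sample peak calls (narrowPeak), per-sample
coverage (bedGraph), a gene/TSS table with TF flags, a replicate-level
expression matrix, a genome FASTA with planted TF binding motifs, a GWAS
SNP table, and per-sample mapped-read totals.

Each enhancer locus lives on its own small contig, so stitching, gene
assignment and linking are exactly separable and the planted truth can be
recovered without ambiguity.  Super-enhancer loci carry three constituent
peaks and one downstream gene; typical-enhancer loci carry a single weak
peak and no gene.  Per-sample signal is drawn from a negative binomial
around a per-class RPM template (dispersion 0 reproduces the template
exactly); gene expression is an affine function of the linked SE's RPM
plus Gaussian noise.  One stable SE can be "amplified" (copy-number
scaled) to mimic an amplified oncogene locus, and its interval is
reported for cutoff masking.

Identical config + seed produce byte-identical output trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crc_network import pwm_scan
from .io_formats import (
    GenomicInterval,
    Peak,
    PWM,
    SnpRecord,
    write_coverage,
    write_fasta,
    write_gene_table,
    write_intervals,
    write_pwm_jaspar,
    write_snp_table,
    write_totals,
    GeneRecord,
    reverse_complement,
)

SAMPLES = ("EtOH_2D", "EtOH_4D", "EtOH_8D", "ATRA_2D", "ATRA_4D", "ATRA_8D")

SE_CLASSES = ("stable", "condition_invariant", "lost", "wave_2d", "wave_4d", "wave_8d")
DYNAMIC_CLASSES = ("lost", "wave_2d", "wave_4d", "wave_8d")

# Per-class mean RPM templates over (EtOH_2D, EtOH_4D, EtOH_8D, ATRA_2D,
# ATRA_4D, ATRA_8D).  Levels are chosen so that active SEs sit far above
# the typical-enhancer background (10-40 RPM), the condition-invariant
# class drifts identically in both arms, the lost class decays strictly
# over the treated days, and each wave class peaks at its day with graded
# shoulders (an abrupt on/off SE is rarer in real H3K27ac time courses
# than a ramped gain/decay).  The control arm drifts by a few percent of
# the dynamic range rather than being bit-identical across days.
CLASS_TEMPLATES: dict[str, tuple[float, ...]] = {
    "stable": (500, 500, 500, 500, 500, 500),
    "condition_invariant": (300, 600, 900, 320, 620, 880),
    "lost": (560, 600, 640, 350, 160, 60),
    "wave_2d": (70, 80, 90, 400, 230, 130),
    "wave_4d": (90, 80, 70, 160, 400, 230),
    "wave_8d": (70, 80, 90, 130, 230, 400),
}

DEFAULT_CLASS_COUNTS = {
    "stable": 143,
    "condition_invariant": 116,
    "lost": 254,
    "wave_2d": 174,
    "wave_4d": 355,
    "wave_8d": 157,
}

# TF quota per class: roughly one in ten SEs drives a TF, with the
# dynamic classes mirroring the 31/17/49/15 split of TF-linked SEs.
DEFAULT_TF_COUNTS = {
    "stable": 10,
    "condition_invariant": 10,
    "lost": 31,
    "wave_2d": 17,
    "wave_4d": 49,
    "wave_8d": 15,
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions.

    ``dispersion`` is the relative count noise: counts are negative
    binomial with mean mu and variance mu + (dispersion * mu)^2, so the
    value is the multiplicative CV of the signal at large mean
    (0 = noiseless).  ``expression_sigma`` is the SD of the Gaussian
    expression noise in normalized-count units (0 = noiseless).
    """

    class_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    n_typical: int = 600
    dispersion: float = 0.0
    expression_sigma: float = 0.0
    n_expression_replicates: int = 3
    expression_intercept: float = 50.0
    expression_slope: float = 1.0
    tf_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TF_COUNTS))
    n_crc_tfs: int = 8
    crc_density: float = 0.5
    n_snps: int = 5
    amplified_locus: bool = True
    amplification_factor: float = 10.0
    total_mapped: float = 2.0e7
    motif_length: int = 8
    scan_threshold_frac: float = 0.8
    # locus geometry (bases)
    se_chrom_len: int = 12_000
    te_chrom_len: int = 4_000
    peak_starts: tuple[int, ...] = (2_000, 4_000, 6_000)
    peak_len: int = 1_000
    tss_offset: int = 10_000
    te_peak_start: int = 1_000

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(SE_CLASSES)
        if unknown:
            raise ValueError(f"unknown SE classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if self.dispersion < 0 or self.expression_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        span = self.peak_starts[-1] + self.peak_len
        if span >= self.tss_offset or self.tss_offset >= self.se_chrom_len:
            raise ValueError("locus geometry inconsistent: peaks/TSS exceed contig")

    @property
    def se_interval_local(self) -> tuple[int, int]:
        """Start/end of the stitched SE within its contig."""
        return self.peak_starts[0], self.peak_starts[-1] + self.peak_len


@dataclass
class TruthTable:
    """Planted ground truth: one row per synthetic SE plus the CRC edges."""

    ses: pd.DataFrame  # se_id, chrom, start, end, class_label, gene_id, symbol,
    #                    corr_sign, is_tf, is_crc_tf, amplified
    edges: pd.DataFrame  # source, target, chrom, offset

    @property
    def class_counts(self) -> dict[str, int]:
        return self.ses["class_label"].value_counts().to_dict()

    @property
    def adjacency(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["source"], self.edges["target"]))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.ses.to_csv(directory / "truth_ses.tsv", sep="\t", index=False)
        self.edges.to_csv(directory / "truth_edges.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "TruthTable":
        directory = Path(directory)
        ses = pd.read_csv(directory / "truth_ses.tsv", sep="\t", dtype={"chrom": str})
        edges = pd.read_csv(directory / "truth_edges.tsv", sep="\t", dtype={"chrom": str})
        return cls(ses=ses, edges=edges)


# ---------------------------------------------------------------------------
# Low-level draws
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: float, dispersion: float) -> float:
    """Negative-binomial count with mean mu and var mu + (dispersion*mu)^2.

    ``dispersion`` is the target coefficient of variation of the count at
    large mean (the NB size parameter is 1/dispersion^2), so dispersion
    0.05 means ~5% multiplicative count noise.  dispersion = 0 is the
    exact noiseless limit (returns mu itself).
    """
    if mu <= 0:
        return 0.0
    if dispersion == 0:
        return float(mu)
    r = 1.0 / dispersion**2
    p = r / (r + mu)
    return float(rng.negative_binomial(r, p))


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def make_consensus_set(
    rng: np.random.Generator, n: int, length: int = 8, min_dist: int = 3
) -> list[str]:
    """Distinct consensus k-mers, pairwise (and vs reverse complements)
    separated by at least ``min_dist`` mismatches."""
    out: list[str] = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 20_000:
            raise RuntimeError("could not build a separated consensus set")
        cand = _random_seq(rng, length)
        ok = _hamming(cand, reverse_complement(cand)) >= min_dist
        for other in out:
            if (
                _hamming(cand, other) < min_dist
                or _hamming(cand, reverse_complement(other)) < min_dist
            ):
                ok = False
                break
        if ok:
            out.append(cand)
    return out


def consensus_counts(consensus: str, strong: int = 97, weak: int = 1) -> np.ndarray:
    """L x 4 count matrix concentrated on the consensus base."""
    counts = np.full((len(consensus), 4), weak, dtype=float)
    for i, base in enumerate(consensus):
        counts[i, "ACGT".index(base)] = strong
    return counts


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------


def plant_motifs(
    sequences: dict[str, str],
    adjacency: list[tuple[str, str]],
    pwms: dict[str, PWM],
    ses: dict[str, GenomicInterval],
    rng: np.random.Generator,
    threshold_frac: float = 0.8,
    max_retries: int = 500,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write, for every edge a -> b, the consensus of PWM_a at a recorded
    offset inside SE_b, on a motif-free background.

    The SE segment background is rejection-sampled until a full scan of
    the segment with every PWM (both strands, at ``threshold_frac`` of
    each PWM's maximum score) finds exactly the planted instances.
    """
    hits_rows = []
    sequences = dict(sequences)
    for target, iv in sorted(ses.items()):
        sources = sorted(a for a, b in adjacency if b == target)
        seg_len = iv.length
        spacing = max(p.matrix.shape[0] for p in pwms.values()) + 24 if pwms else 32
        if sources and 100 + len(sources) * spacing > seg_len:
            raise ValueError(f"SE of {target} too short for {len(sources)} motifs")
        offsets = {a: 100 + k * spacing for k, a in enumerate(sources)}

        planted_ok = False
        for _ in range(max_retries):
            seg = list(_random_seq(rng, seg_len))
            for a in sources:
                cons = pwms[a].consensus
                off = offsets[a]
                seg[off : off + len(cons)] = cons
            seg_str = "".join(seg)
            expected = {
                (a, iv.start + offsets[a], "+") for a in sources
            }
            found = set()
            clean = True
            for name, pwm in pwms.items():
                thr = threshold_frac * pwm.max_score
                for hit in pwm_scan(seg_str, pwm, thr, chrom=iv.chrom, offset=iv.start):
                    key = (name, hit.interval.start, hit.strand)
                    if key in expected:
                        found.add(key)
                    else:
                        clean = False
                        break
                if not clean:
                    break
            if clean and found == expected:
                planted_ok = True
                break
        if not planted_ok:
            raise RuntimeError(f"could not build a motif-clean SE for {target}")

        chrom_seq = sequences[iv.chrom]
        sequences[iv.chrom] = chrom_seq[: iv.start] + seg_str + chrom_seq[iv.end :]
        for a in sources:
            hits_rows.append(
                {
                    "source": a,
                    "target": target,
                    "chrom": iv.chrom,
                    "offset": iv.start + offsets[a],
                }
            )
    edges = pd.DataFrame(hits_rows, columns=["source", "target", "chrom", "offset"])
    return sequences, edges


# ---------------------------------------------------------------------------
# Profile-level simulation (no files) -- used for focused experiments
# ---------------------------------------------------------------------------


def simulate_class_profiles(
    config: SimulationConfig,
    seed: int,
    classes: tuple[str, ...] = DYNAMIC_CLASSES,
) -> tuple[pd.DataFrame, pd.Series]:
    """RPM profile matrix for the requested classes under the configured
    noise, without writing any files.  Mirrors the bundle's count model:
    per-constituent-peak negative-binomial counts, summed and RPM
    normalized.  Returns (profiles, class labels)."""
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    peak_lens = np.full(len(config.peak_starts), config.peak_len, dtype=float)
    frac = peak_lens / peak_lens.sum()
    i = 0
    for cls in classes:
        template = np.array(CLASS_TEMPLATES[cls], dtype=float)
        for _ in range(config.class_counts.get(cls, 0)):
            i += 1
            scale = rng.uniform(0.8, 1.25)
            rpm = []
            for s_idx in range(len(SAMPLES)):
                mu_locus = template[s_idx] * scale * config.total_mapped / 1e6
                count = sum(
                    _nb_draw(rng, mu_locus * f, config.dispersion) for f in frac
                )
                rpm.append(count * 1e6 / config.total_mapped)
            rows.append(rpm)
            labels.append(cls)
            ids.append(f"se_{i:04d}")
    profiles = pd.DataFrame(rows, index=ids, columns=list(SAMPLES))
    return profiles, pd.Series(labels, index=ids, name="class_label")


def simulate_expression_row(
    rpm_profile: np.ndarray,
    rng: np.random.Generator,
    sigma: float,
    n_replicates: int = 3,
    intercept: float = 50.0,
    slope: float = 1.0,
    sign: int = 1,
) -> np.ndarray:
    """Replicate-level expression for one gene linked to one SE:
    a + sign*b*RPM + N(0, sigma), clipped at 0.  Column order is
    sample-major: all replicates of SAMPLES[0], then SAMPLES[1], ..."""
    values = []
    for rpm in np.asarray(rpm_profile, dtype=float):
        mean = intercept + sign * slope * rpm
        for _ in range(n_replicates):
            noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            values.append(max(0.0, mean + noise))
    return np.array(values)


def expression_columns(n_replicates: int) -> list[str]:
    return [f"{s}_rep{j + 1}" for s in SAMPLES for j in range(n_replicates)]


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


def simulate_bundle(
    config: SimulationConfig, seed: int, out_dir: str | Path
) -> tuple[dict[str, str], TruthTable]:
    """Emit a complete synthetic input bundle and its ground truth.

    Returns (manifest dict, TruthTable); the manifest (also written as
    manifest.yaml) maps logical names to the emitted file paths.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)

    se_start, se_end = config.se_interval_local

    # --- locus table -------------------------------------------------------
    locus_rows = []
    i = 0
    for cls in SE_CLASSES:
        for _ in range(config.class_counts.get(cls, 0)):
            i += 1
            locus_rows.append({"se_id": f"se_{i:04d}", "chrom": f"se_{i:04d}", "class_label": cls})
    n_se = i
    if n_se == 0:
        raise ValueError("no SE loci requested")

    ses = pd.DataFrame(locus_rows)
    ses["start"] = se_start
    ses["end"] = se_end
    ses["scale"] = rng.uniform(0.8, 1.25, n_se)
    ses["amplified"] = False
    if config.amplified_locus:
        stable_idx = ses.index[ses["class_label"] == "stable"]
        if len(stable_idx) == 0:
            raise ValueError("amplified locus requires at least one stable SE")
        amp = stable_idx[0]
        ses.loc[amp, "scale"] *= config.amplification_factor
        ses.loc[amp, "amplified"] = True

    te_levels = rng.uniform(10, 40, config.n_typical)

    # --- TF flags and genes -------------------------------------------------
    ses["is_tf"] = False
    for cls in SE_CLASSES:
        members = ses.index[ses["class_label"] == cls].to_numpy()
        quota = min(config.tf_counts.get(cls, 0), len(members))
        if quota:
            chosen = rng.choice(members, size=quota, replace=False)
            ses.loc[np.sort(chosen), "is_tf"] = True

    tf_counter, gene_counter = 0, 0
    gene_ids, symbols = [], []
    for flag in ses["is_tf"]:
        if flag:
            tf_counter += 1
            symbols.append(f"TF{tf_counter:03d}")
        else:
            gene_counter += 1
            symbols.append(f"GENE{gene_counter:04d}")
    gene_ids = [f"g_{sid}" for sid in ses["se_id"]]
    ses["gene_id"] = gene_ids
    ses["symbol"] = symbols
    ses["corr_sign"] = 1

    genes = [
        GeneRecord(
            gene_id=row.gene_id,
            symbol=row.symbol,
            tss=GenomicInterval(row.chrom, config.tss_offset, config.tss_offset + 1, "+"),
            is_tf=bool(row.is_tf),
        )
        for row in ses.itertuples(index=False)
    ]

    # --- CRC selection ------------------------------------------------------
    dyn_tf = ses.index[(ses["is_tf"]) & (ses["class_label"].isin(DYNAMIC_CLASSES))].to_numpy()
    n_crc = min(config.n_crc_tfs, len(dyn_tf))
    crc_idx = np.sort(rng.choice(dyn_tf, size=n_crc, replace=False)) if n_crc else np.array([], dtype=int)
    ses["is_crc_tf"] = False
    ses.loc[crc_idx, "is_crc_tf"] = True
    crc_tfs = list(ses.loc[crc_idx, "symbol"])

    consensi = make_consensus_set(rng, n_crc, length=config.motif_length)
    pwm_counts = {tf: consensus_counts(cons) for tf, cons in zip(crc_tfs, consensi)}
    pwms = {
        tf: PWM.from_counts(tf, counts, pseudocount=0.01)
        for tf, counts in pwm_counts.items()
    }
    adjacency = [
        (a, b)
        for a in crc_tfs
        for b in crc_tfs
        if rng.uniform() < config.crc_density
    ]

    # --- per-sample counts, peaks and coverage ------------------------------
    templates = {cls: np.array(t, dtype=float) for cls, t in CLASS_TEMPLATES.items()}
    peak_lens = np.full(len(config.peak_starts), config.peak_len, dtype=float)
    frac = peak_lens / peak_lens.sum()

    profiles_truth = np.zeros((n_se, len(SAMPLES)))
    for s_idx, sample in enumerate(SAMPLES):
        peak_records: list[Peak] = []
        cov_rows: list[tuple[str, int, int, float]] = []
        for row_idx, row in enumerate(ses.itertuples(index=False)):
            mu_locus = templates[row.class_label][s_idx] * row.scale * config.total_mapped / 1e6
            locus_count = 0.0
            for k, p_start in enumerate(config.peak_starts):
                c = _nb_draw(rng, mu_locus * frac[k], config.dispersion)
                locus_count += c
                density = c / config.peak_len
                iv = GenomicInterval(row.chrom, p_start, p_start + config.peak_len)
                peak_records.append(
                    Peak(interval=iv, sample_id=sample, signal=density,
                         name=f"{row.se_id}_p{k + 1}")
                )
                if c > 0:
                    cov_rows.append((row.chrom, p_start, p_start + config.peak_len, density))
            profiles_truth[row_idx, s_idx] = locus_count * 1e6 / config.total_mapped
        for t_idx in range(config.n_typical):
            chrom = f"te_{t_idx + 1:04d}"
            mu = te_levels[t_idx] * config.total_mapped / 1e6
            c = _nb_draw(rng, mu, config.dispersion)
            density = c / config.peak_len
            iv = GenomicInterval(chrom, config.te_peak_start, config.te_peak_start + config.peak_len)
            peak_records.append(Peak(interval=iv, sample_id=sample, signal=density, name=chrom))
            if c > 0:
                cov_rows.append((chrom, config.te_peak_start, config.te_peak_start + config.peak_len, density))
        write_intervals(peak_records, out / "peaks" / f"{sample}.narrowPeak", format="narrowpeak")
        write_coverage(cov_rows, out / "coverage" / f"{sample}.bedGraph")

    # --- genome with planted motifs -----------------------------------------
    sequences: dict[str, str] = {}
    for row in ses.itertuples(index=False):
        sequences[row.chrom] = _random_seq(rng, config.se_chrom_len)
    for t_idx in range(config.n_typical):
        sequences[f"te_{t_idx + 1:04d}"] = _random_seq(rng, config.te_chrom_len)

    tf_se_map = {
        row.symbol: GenomicInterval(row.chrom, se_start, se_end)
        for row in ses.itertuples(index=False)
        if row.is_crc_tf
    }
    sequences, edges = plant_motifs(
        sequences, adjacency, pwms, tf_se_map, rng,
        threshold_frac=config.scan_threshold_frac,
    )
    write_fasta(sequences, out / "genome.fa")
    write_pwm_jaspar(pwm_counts, out / "pwms.jaspar")

    # --- expression ----------------------------------------------------------
    expr_rows = {}
    for row_idx, row in enumerate(ses.itertuples(index=False)):
        expr_rows[row.gene_id] = simulate_expression_row(
            profiles_truth[row_idx],
            rng,
            sigma=config.expression_sigma,
            n_replicates=config.n_expression_replicates,
            intercept=config.expression_intercept,
            slope=config.expression_slope,
            sign=int(row.corr_sign),
        )
    expr = pd.DataFrame.from_dict(
        expr_rows, orient="index",
        columns=expression_columns(config.n_expression_replicates),
    )
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id",
                float_format="%.10g")

    # --- SNPs ----------------------------------------------------------------
    dyn_idx = ses.index[ses["class_label"].isin(DYNAMIC_CLASSES)].to_numpy()
    lost_idx = ses.index[ses["class_label"] == "lost"].to_numpy()
    n_snps = min(config.n_snps, len(dyn_idx))
    snps: list[SnpRecord] = []
    if n_snps:
        first = lost_idx[0] if len(lost_idx) else dyn_idx[0]
        rest_pool = dyn_idx[dyn_idx != first]
        chosen = [first] + list(
            np.sort(rng.choice(rest_pool, size=n_snps - 1, replace=False))
            if n_snps > 1 else []
        )
        for j, se_row in enumerate(chosen):
            row = ses.loc[se_row]
            pos = int(rng.integers(se_start, se_end))
            if j == 0:
                # an rs2168101-like protective variant inside a lost SE
                snps.append(SnpRecord("rs2168101", GenomicInterval(row.chrom, pos, pos + 1),
                                      p_value=3.18e-16, odds_ratio=0.70, alleles="G>T"))
            else:
                snps.append(
                    SnpRecord(
                        f"rs{900000 + j}",
                        GenomicInterval(row.chrom, pos, pos + 1),
                        p_value=float(10 ** rng.uniform(-12, -6)),
                        odds_ratio=float(rng.uniform(0.6, 1.6)),
                        alleles="A>G",
                    )
                )
    write_snp_table(snps, out / "snps.tsv", one_based=True)

    # --- remaining tables ----------------------------------------------------
    write_gene_table(genes, out / "genes.tsv")
    totals = {s: config.total_mapped for s in SAMPLES}
    write_totals(totals, out / "totals.tsv")

    amplified_ivs = [
        GenomicInterval(row.chrom, se_start, se_end)
        for row in ses.itertuples(index=False)
        if row.amplified
    ]
    with open(out / "amplified.bed", "w") as fh:
        for iv in amplified_ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    truth = TruthTable(
        ses=ses[
            ["se_id", "chrom", "start", "end", "class_label", "gene_id", "symbol",
             "corr_sign", "is_tf", "is_crc_tf", "amplified"]
        ].copy(),
        edges=edges,
    )
    truth.save(out)

    manifest = {
        "seed": int(seed),
        "samples": list(SAMPLES),
        "genome": "genome.fa",
        "peaks": {s: f"peaks/{s}.narrowPeak" for s in SAMPLES},
        "coverage": {s: f"coverage/{s}.bedGraph" for s in SAMPLES},
        "genes": "genes.tsv",
        "expression": "expression.tsv",
        "totals": "totals.tsv",
        "snps": "snps.tsv",
        "pwms": "pwms.jaspar",
        "amplified": "amplified.bed",
        "truth_ses": "truth_ses.tsv",
        "truth_edges": "truth_edges.tsv",
        "n_se": int(n_se),
        "n_typical": int(config.n_typical),
        "dispersion": float(config.dispersion),
        "expression_sigma": float(config.expression_sigma),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest, truth
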