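"""Linking dynamic super-enhancers to genes through expression correlation.

A candidate SE-gene pair (from proximity assignment) is kept when the
Pearson correlation between the SE's H3K27ac RPM profile and the gene's
mRNA expression over the matched condition/day grid reaches a threshold
(default signed r >= 0.45; an r^2 variant is available).  Correlation is
computed at replicate resolution: each expression replicate of a
condition/day is paired with that condition/day's ChIP signal, which
keeps the permutation null sharp when the grid itself has few points.
Links are then restricted to transcription factors, and per-cluster
expression shifts are tested with a paired two-tailed t-test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneRecord

_SAMPLE_RE = re.compile(
    r"^(?P<condition>[A-Za-z0-9]+)_(?P<day>\d+)D(?:_rep(?P<rep>\d+))?$"
)


def parse_sample_name(name: str) -> tuple[str, int, int]:
    """Parse 'COND_<day>D[_rep<j>]' into (condition, day, replicate)."""
    m = _SAMPLE_RE.match(name)
    if not m:
        raise ValueError(
            f"sample name {name!r} does not match 'COND_<day>D[_rep<j>]'"
        )
    return m["condition"], int(m["day"]), int(m["rep"] or 1)


@dataclass
class SEGeneLink:
    """One SE-gene candidate pair with its correlation and pass flag."""

    se_id: str
    gene_id: str
    distance: int
    r: float
    passes: bool
    wave_label: str = "none"
    is_tf: bool = False


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def _passes(r: float, r_min: float, comparator: str, stat: str) -> bool:
    if np.isnan(r):
        return False
    value = r * r if stat == "r2" else r
    if comparator == ">":
        return value > r_min
    if comparator == ">=":
        return value >= r_min
    raise ValueError(f"unknown comparator {comparator!r}")


def match_samples(
    chip_samples: list[str], expr_samples: list[str]
) -> list[tuple[str, str]]:
    """Pair each expression sample with the ChIP sample of the same
    condition and day.  Every expression replicate becomes one matched
    point; errors list any expression sample with no ChIP counterpart."""
    chip_by_key = {}
    for s in chip_samples:
        cond, day, _ = parse_sample_name(s)
        chip_by_key[(cond, day)] = s
    pairs = []
    unmatched = []
    for s in expr_samples:
        cond, day, _ = parse_sample_name(s)
        chip = chip_by_key.get((cond, day))
        if chip is None:
            unmatched.append(s)
        else:
            pairs.append((chip, s))
    if unmatched:
        raise ValueError(f"expression samples with no matching ChIP sample: {unmatched}")
    if not pairs:
        raise ValueError("no matched samples between ChIP and expression")
    return pairs


def link_and_filter(
    profiles: pd.DataFrame,
    expr: pd.DataFrame,
    pairs: list[tuple[str, str, int]],
    r_min: float = 0.45,
    comparator: str = ">=",
    stat: str = "r",
    classification: pd.DataFrame | None = None,
) -> list[SEGeneLink]:
    """Correlate SE profiles with gene expression over matched samples.

    ``pairs`` is a list of (se_id, gene_id, distance) candidates.  The
    pass rule defaults to signed Pearson r >= ``r_min``; ``stat='r2'``
    switches to r^2.  Constant profiles or expression rows yield r = NaN
    and never pass.
    """
    if not (-1 <= r_min <= 1) and stat == "r":
        raise ValueError("r_min outside [-1, 1]")
    matched = match_samples(list(profiles.columns), list(expr.columns))
    chip_cols = [c for c, _ in matched]
    expr_cols = [e for _, e in matched]
    links = []
    for se_id, gene_id, distance in pairs:
        if se_id not in profiles.index:
            raise KeyError(f"SE {se_id} has no profile")
        if gene_id not in expr.index:
            raise KeyError(f"gene {gene_id} missing from expression matrix")
        x = profiles.loc[se_id, chip_cols].to_numpy(dtype=float)
        y = expr.loc[gene_id, expr_cols].to_numpy(dtype=float)
        r = pearson_r(x, y)
        wave = "none"
        if classification is not None and se_id in classification.index:
            wave = str(classification.loc[se_id, "wave_label"])
        links.append(
            SEGeneLink(
                se_id=se_id,
                gene_id=gene_id,
                distance=distance,
                r=r,
                passes=_passes(r, r_min, comparator, stat),
                wave_label=wave,
            )
        )
    return links


def restrict_to_tfs(
    links: list[SEGeneLink], genes: list[GeneRecord]
) -> tuple[list[SEGeneLink], pd.DataFrame]:
    """Keep links whose gene is flagged as a transcription factor.

    Returns the TF links (is_tf set) and a per-wave summary with the TF
    link count, total link count and TF fraction.
    """
    tf_flag = {g.gene_id: g.is_tf for g in genes}
    for link in links:
        if link.gene_id not in tf_flag:
            raise KeyError(f"gene {link.gene_id} absent from annotation")
        link.is_tf = tf_flag[link.gene_id]
    kept = [l for l in links if l.is_tf]

    rows = []
    waves = sorted({l.wave_label for l in links})
    for wave in waves:
        total = sum(1 for l in links if l.wave_label == wave)
        n_tf = sum(1 for l in kept if l.wave_label == wave)
        rows.append(
            {
                "wave_label": wave,
                "n_links": total,
                "n_tf_links": n_tf,
                "tf_fraction": n_tf / total if total else 0.0,
            }
        )
    return kept, pd.DataFrame(rows)


def links_table(links: list[SEGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "se_id": l.se_id,
                "gene_id": l.gene_id,
                "wave_label": l.wave_label,
                "distance": l.distance,
                "r": l.r,
                "passes": l.passes,
                "is_tf": l.is_tf,
            }
            for l in links
        ]
    )


def paired_group_test(values_t: np.ndarray, values_ref: np.ndarray) -> tuple[float, float]:
    """Paired two-tailed t-test: t = mean(d) / (SD(d)/sqrt(n)), df = n-1.

    Identical vectors return (0, 1).  A nonzero constant difference vector
    has zero variance and no finite t, which is an error.
    """
    a = np.asarray(values_t, dtype=float)
    b = np.asarray(values_ref, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if d.std(ddof=1) == 0:
        raise ValueError("degenerate paired test: zero-variance differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
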