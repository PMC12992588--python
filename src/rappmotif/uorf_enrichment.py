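"""uORF / downstream-gene enrichment testing.

Pairs each small motif-encoding ORF (the candidate arrest peptide) with
its same-strand downstream gene, groups pairs by the downstream
product annotation, and asks which annotation groups are enriched among
target-motif uORFs (RGPP, RAPP) relative to the arrest-dead control
motifs (AGPP, AAPP).  Fold enrichment is proportion-normalized,
significance is a two-sided Fisher exact test computed from the
hypergeometric distribution in log space, and the family of groups in
one target/control comparison is Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import GeneFeature

UORF_KEYWORDS = ("unknown", "hypothetical", "uncharacterized")
DEFAULT_BH_THRESHOLD = 0.01

#: Relative slack when comparing table probabilities in the two-sided
#: minimum-likelihood rule (guards against floating-point ties).
_TWO_SIDED_SLACK = 1e-7


@dataclass(frozen=True)
class GenePair:
    """A candidate uORF and its same-strand downstream gene."""

    uorf: GeneFeature
    downstream: GeneFeature
    motif: str
    uorf_protein_length: int
    intergenic_distance: int

    @property
    def group_key(self) -> str:
        return normalize_annotation(self.downstream.product_annotation)


@dataclass
class EnrichmentResult:
    """2x2 counts and test results for one annotation group.

    a/b: target-motif uORFs inside/outside the group; c/d: the same for
    the control motif.  ``fold_enrichment`` is (a/(a+b)) / (c/(c+d)),
    flagged infinite when c = 0 (no control uORF in the group)."""

    group_key: str
    a: int
    b: int
    c: int
    d: int
    fold_enrichment: float
    infinite_fold: bool
    p_value: float
    p_adjusted: float
    significant: bool


def normalize_annotation(annotation: str) -> str:
    """Lowercase, collapse whitespace, strip trailing punctuation.

    Exact normalized-string match defines a group; no fuzzy matching
    ("TonB-dependent receptor" and "TonB dependent receptor" differ).
    """
    s = re.sub(r"\s+", " ", annotation.strip().lower())
    return s.rstrip(".,;: ")


def find_downstream(
    features: Sequence[GeneFeature],
    uorf: GeneFeature,
    max_gap: int | None = None,
    allow_overlap: int = 0,
) -> GeneFeature | None:
    """Nearest same-contig, same-strand CDS downstream in translation
    direction.

    On the + strand this is the feature with minimal start > uorf.end;
    on the - strand, maximal end < uorf.start.  ``allow_overlap`` moves
    the boundary inward by that many bases; ``max_gap`` (bases between
    uORF stop and downstream start) drops distant candidates.
    ``features`` must be sorted by (contig, start).
    """
    best: GeneFeature | None = None
    for feat in features:
        if feat.contig != uorf.contig or feat.strand != uorf.strand:
            continue
        if feat.start == uorf.start and feat.end == uorf.end:
            continue
        if uorf.strand == "+":
            if feat.start > uorf.end - allow_overlap:
                if best is None or feat.start < best.start:
                    best = feat
        else:
            if feat.end < uorf.start + allow_overlap:
                if best is None or feat.end > best.end:
                    best = feat
    if best is None:
        return None
    gap = intergenic_distance(uorf, best)
    if max_gap is not None and gap > max_gap:
        return None
    return best


def intergenic_distance(uorf: GeneFeature, downstream: GeneFeature) -> int:
    """Downstream 5' start minus uORF 3' end, in translation direction
    (negative when the genes overlap)."""
    if uorf.strand == "+":
        return downstream.start - uorf.end
    return uorf.start - downstream.end


def select_uorfs(
    pairs: Iterable[GenePair],
    uorf_keywords: Sequence[str] = UORF_KEYWORDS,
    length_cap: int = 300,
) -> list[GenePair]:
    """Keep pairs whose uORF looks like an unannotated small ORF and
    whose downstream gene has a usable functional annotation.

    The uORF product must (case-insensitively) contain one of the
    keywords (unknown / hypothetical / uncharacterized) and be shorter
    than ``length_cap`` residues; the downstream annotation must be
    non-empty and must not contain "unknown".
    """
    kept = []
    for pair in pairs:
        if pair.uorf_protein_length >= length_cap:
            continue
        up = pair.uorf.product_annotation.lower()
        if not any(k in up for k in uorf_keywords):
            continue
        down = pair.downstream.product_annotation.strip()
        if not down or "unknown" in down.lower():
            continue
        kept.append(pair)
    return kept


def group_by_annotation(pairs: Iterable[GenePair]) -> dict[str, list[GenePair]]:
    """Partition pairs by normalized downstream annotation."""
    groups: dict[str, list[GenePair]] = {}
    for pair in pairs:
        groups.setdefault(pair.group_key, []).append(pair)
    return groups


@lru_cache(maxsize=65536)
def _hypergeom_logpmf_table(n: int, r1: int, c1: int) -> tuple[int, int, tuple[float, ...]]:
    """log P(X = x) for X ~ Hypergeom(n, r1, c1) over its support.

    Returns (x_min, x_max, logpmf values).  This is the distribution of
    the top-left cell of a 2x2 table with fixed margins.
    """
    x_min = max(0, c1 - (n - r1))
    x_max = min(r1, c1)
    xs = np.arange(x_min, x_max + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(xs + 1) - gammaln(r1 - xs + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - xs + 1) - gammaln(n - r1 - (c1 - xs) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return int(x_min), int(x_max), tuple(float(v) for v in logpmf)


def fisher_exact(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for the 2x2 table [[a, b], [c, d]].

    Computed from exact hypergeometric probabilities in log space.
    ``two-sided`` uses the minimum-likelihood rule (sum over tables with
    the same margins whose probability does not exceed the observed
    table's, with a small relative slack) — the R default; ``greater``
    is the one-sided test for enrichment of a.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("negative cell count")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    x_min, x_max, logpmf = _hypergeom_logpmf_table(n, r1, c1)
    logpmf = np.array(logpmf)
    obs = logpmf[a - x_min]
    if alternative == "greater":
        mask = np.arange(x_min, x_max + 1) >= a
    elif alternative == "less":
        mask = np.arange(x_min, x_max + 1) <= a
    elif alternative == "two-sided":
        mask = logpmf <= obs + math.log1p(_TWO_SIDED_SLACK)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    # log-sum-exp over the selected tables
    sel = logpmf[mask]
    m = sel.max()
    p = float(np.exp(m) * np.exp(sel - m).sum())
    return min(p, 1.0)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up BH adjustment, returned in input order.

    q(i) = min_{j >= i} ( p(j) * m / j ) over the ascending order,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    # q >= p holds mathematically; clamp away float rounding at the j=m term
    out = np.maximum(out, p)
    return out.tolist()


def enrichment_table(
    target_pairs: Sequence[GenePair],
    control_pairs: Sequence[GenePair],
    alternative: str = "two-sided",
    significance_threshold: float = DEFAULT_BH_THRESHOLD,
) -> list[EnrichmentResult]:
    """Per-annotation-group 2x2 tests of target vs control uORF counts.

    One result per group present in either motif's pairs.  The BH
    family is all groups of this single comparison.  Groups with no
    control uORF keep an infinite-fold flag rather than being dropped
    or pseudocounted.
    """
    n_target, n_control = len(target_pairs), len(control_pairs)
    if n_target == 0 or n_control == 0:
        raise ValueError("both motifs need at least one uORF pair")
    tg = group_by_annotation(target_pairs)
    cg = group_by_annotation(control_pairs)
    groups = sorted(set(tg) | set(cg))
    rows = []
    for g in groups:
        a = len(tg.get(g, []))
        c = len(cg.get(g, []))
        b, d = n_target - a, n_control - c
        if c > 0:
            fold = (a / n_target) / (c / n_control)
            infinite = False
        else:
            fold = math.inf
            infinite = True
        p = fisher_exact(a, b, c, d, alternative=alternative)
        rows.append((g, a, b, c, d, fold, infinite, p))
    adj = benjamini_hochberg([r[7] for r in rows])
    results = [
        EnrichmentResult(
            group_key=g, a=a, b=b, c=c, d=d,
            fold_enrichment=fold, infinite_fold=infinite,
            p_value=p, p_adjusted=q, significant=q < significance_threshold,
        )
        for (g, a, b, c, d, fold, infinite, p), q in zip(rows, adj)
    ]
    results.sort(key=lambda r: (-r.fold_enrichment, r.p_adjusted, r.group_key))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group_key,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "fold_enrichment": r.fold_enrichment,
                "infinite_fold": r.infinite_fold,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def pair_uorfs(
    features: Sequence[GeneFeature],
    motif_by_protein: Mapping[str, str],
    protein_lengths: Mapping[str, int],
    max_gap: int | None = None,
    allow_overlap: int = 0,
) -> list[GenePair]:
    """Build GenePairs for every feature whose protein carries a motif.

    ``motif_by_protein`` maps protein_id -> motif for the uORF
    candidates (from motif_census.scan_motifs); features without an
    entry are treated only as potential downstream genes.
    """
    # per-(contig, strand) indices so pairing stays near-linear
    by_key: dict[tuple[str, str], list[GeneFeature]] = {}
    for feat in features:
        by_key.setdefault((feat.contig, feat.strand), []).append(feat)
    starts_idx: dict[tuple[str, str], tuple[list[int], list[GeneFeature]]] = {}
    ends_idx: dict[tuple[str, str], tuple[list[int], list[GeneFeature]]] = {}
    for key, feats in by_key.items():
        by_start = sorted(feats, key=lambda f: f.start)
        starts_idx[key] = ([f.start for f in by_start], by_start)
        by_end = sorted(feats, key=lambda f: f.end)
        ends_idx[key] = ([f.end for f in by_end], by_end)

    def _nearest_downstream(uorf: GeneFeature) -> GeneFeature | None:
        key = (uorf.contig, uorf.strand)
        if uorf.strand == "+":
            starts, feats = starts_idx[key]
            i = bisect_right(starts, uorf.end - allow_overlap)
            while i < len(feats):
                f = feats[i]
                if not (f.start == uorf.start and f.end == uorf.end):
                    return f
                i += 1
            return None
        ends, feats = ends_idx[key]
        i = bisect_left(ends, uorf.start + allow_overlap) - 1
        while i >= 0:
            f = feats[i]
            if not (f.start == uorf.start and f.end == uorf.end):
                return f
            i -= 1
        return None

    pairs = []
    for feat in features:
        if feat.protein_id is None or feat.protein_id not in motif_by_protein:
            continue
        down = _nearest_downstream(feat)
        if down is not None and max_gap is not None:
            if intergenic_distance(feat, down) > max_gap:
                down = None
        if down is None:
            continue
        pairs.append(
            GenePair(
                uorf=feat,
                downstream=down,
                motif=motif_by_protein[feat.protein_id],
                uorf_protein_length=protein_lengths.get(feat.protein_id, 0),
                intergenic_distance=intergenic_distance(feat, down),
            )
        )
    return pairs
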