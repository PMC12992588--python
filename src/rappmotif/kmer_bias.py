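"""Composition-normalized tetrapeptide frequency bias.

The central statistic: for a proteome, every overlapping window of k
consecutive standard residues is counted; the observed frequency of a
pattern (windows equal to it / total windows) is divided by the
frequency expected from the proteome's single-residue composition
(the product of the k per-letter frequencies).  A bias below 1 means
the pattern is underrepresented relative to what amino-acid usage
alone predicts — the signature of a translation-impeding motif that
selection has purged.

Per-clade aggregation (ECDFs, means/medians over genomes, the
lowest-mean underrepresentation ranking) and the per-phylum
1000-genome subsample live here too.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Proteome

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}
_NONSTANDARD_RE = re.compile(f"[^{STANDARD_AA}]")

#: Seed of the per-phylum genome subsample (GTDB release number).
DEFAULT_SUBSAMPLE_SEED = 214


@dataclass(frozen=True)
class PatternStats:
    """Observed/expected frequency and bias of one pattern in one proteome.

    ``bias`` is None (undefined) when the expected frequency is zero or
    the proteome has no valid windows; it is 0.0 — a real observation —
    when the pattern simply never occurs but was expected to.
    """

    genome_id: str
    pattern: str
    observed_count: int
    total_windows: int
    observed_freq: float
    expected_freq: float
    bias: float | None

    @property
    def defined(self) -> bool:
        return self.bias is not None


@dataclass
class CladeBiasSummary:
    """Distribution of one pattern's bias across a clade's genomes."""

    clade: str
    pattern: str
    n_genomes: int
    mean_bias: float
    median_bias: float
    fraction_zero: float
    ecdf_points: list[tuple[float, float]]


def all_patterns(k: int = 4) -> list[str]:
    """Enumerate the full pattern universe over the 20 standard letters."""
    return ["".join(p) for p in itertools.product(STANDARD_AA, repeat=k)]


def _standard_runs(sequence: str) -> list[str]:
    """Maximal substrings made solely of standard letters.

    Windows straddling a non-standard letter (X, B, Z, J, U, O, ...)
    are excluded from both counts and the window total, so splitting on
    those letters and counting within each run is exact.
    """
    return [run for run in _NONSTANDARD_RE.split(sequence) if run]


def count_kmers(proteome: Proteome, k: int = 4) -> tuple[Counter, int]:
    """Sliding-window k-mer counts and the total number of valid windows.

    Overlapping windows all count.  Proteins (or standard-letter runs)
    shorter than k contribute no windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    total = 0
    for rec in proteome:
        for run in _standard_runs(rec.sequence):
            n = len(run) - k + 1
            if n <= 0:
                continue
            total += n
            for i in range(n):
                counts[run[i : i + k]] += 1
    return counts, total


def composition(proteome: Proteome) -> np.ndarray:
    """Per-letter frequency over all standard residues of the proteome.

    Returns a length-20 vector indexed like STANDARD_AA, summing to 1.
    Non-standard letters are excluded from numerator and denominator.
    """
    counts = Counter()
    for rec in proteome:
        counts.update(rec.sequence)
    vec = np.array([counts.get(a, 0) for a in STANDARD_AA], dtype=float)
    total = vec.sum()
    if total == 0:
        raise ValueError(f"proteome {proteome.genome_id!r} has no standard residues")
    return vec / total


def expected_frequency(pattern: str, comp: np.ndarray) -> float:
    """Product of the composition frequencies of the pattern's letters."""
    try:
        idx = [_AA_INDEX[a] for a in pattern]
    except KeyError as exc:
        raise ValueError(f"non-standard letter {exc.args[0]!r} in pattern {pattern!r}")
    return float(np.prod(comp[idx]))


def frequency_bias(proteome: Proteome, pattern: str, k: int | None = None) -> PatternStats:
    """Observed/expected frequency ratio of one pattern in one proteome."""
    k = len(pattern) if k is None else k
    if len(pattern) != k:
        raise ValueError(f"pattern {pattern!r} is not length {k}")
    counts, total = count_kmers(proteome, k)
    comp = composition(proteome)
    exp = expected_frequency(pattern, comp)
    obs_count = counts.get(pattern, 0)
    if total == 0:
        return PatternStats(proteome.genome_id, pattern, 0, 0, 0.0, exp, None)
    obs_freq = obs_count / total
    bias = obs_freq / exp if exp > 0 else None
    return PatternStats(
        proteome.genome_id, pattern, obs_count, total, obs_freq, exp, bias
    )


def bias_table(
    proteome: Proteome,
    patterns: Sequence[str] | None = None,
    k: int = 4,
    per_protein: bool = False,
) -> pd.DataFrame:
    """PatternStats for many (or all 20^k) patterns of one proteome.

    Expected frequencies for the full universe are computed as the
    k-fold outer product of the composition vector, so the full
    160,000-pattern table is cheap.  ``per_protein=True`` switches the
    observed count to the number of motif-containing proteins
    (sensitivity mode; the window count is the primary definition).
    """
    counts, total = count_kmers(proteome, k)
    comp = composition(proteome)
    if per_protein:
        presence: Counter = Counter()
        for rec in proteome:
            seen = set()
            for run in _standard_runs(rec.sequence):
                for i in range(len(run) - k + 1):
                    seen.add(run[i : i + k])
            presence.update(seen)
        counts = presence
    if patterns is None:
        patterns = all_patterns(k)
        expected = comp.copy()
        for _ in range(k - 1):
            expected = np.multiply.outer(expected, comp).ravel()
    else:
        expected = np.array([expected_frequency(p, comp) for p in patterns])
    observed = np.array([counts.get(p, 0) for p in patterns], dtype=np.int64)
    obs_freq = observed / total if total > 0 else np.zeros(len(observed))
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = np.where(expected > 0, obs_freq / np.where(expected > 0, expected, 1), np.nan)
    if total == 0:
        bias = np.full(len(observed), np.nan)
    return pd.DataFrame(
        {
            "genome_id": proteome.genome_id,
            "clade": proteome.clade,
            "pattern": list(patterns),
            "observed_count": observed,
            "total_windows": total,
            "observed_freq": obs_freq,
            "expected_freq": expected,
            "bias": bias,
        }
    )


def subsample_genomes(
    genome_ids: Sequence[str],
    clade_map: Mapping[str, str],
    cap: int = 1000,
    seed: int = DEFAULT_SUBSAMPLE_SEED,
) -> dict[str, list[str]]:
    """Per-clade genome lists, clades above ``cap`` reduced by a seeded
    uniform draw without replacement (deterministic for a fixed seed)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    by_clade: dict[str, list[str]] = {}
    for gid in genome_ids:
        clade = clade_map.get(gid)
        if clade is None:
            continue
        by_clade.setdefault(clade, []).append(gid)
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for clade in sorted(by_clade):
        members = sorted(by_clade[clade])
        if len(members) > cap:
            idx = rng.choice(len(members), size=cap, replace=False)
            members = [members[i] for i in sorted(idx)]
        out[clade] = members
    return out


def ecdf(values: Sequence[float]) -> list[tuple[float, float]]:
    """Right-continuous ECDF as (value, cumulative fraction) step points."""
    xs = np.sort(np.asarray(values, dtype=float))
    n = len(xs)
    if n == 0:
        raise ValueError("no values for ECDF")
    points = []
    for x in np.unique(xs):
        frac = np.searchsorted(xs, x, side="right") / n
        points.append((float(x), float(frac)))
    return points


def ecdf_at(points: Sequence[tuple[float, float]], x: float) -> float:
    """Evaluate a step ECDF at x (fraction of observations <= x)."""
    val = 0.0
    for xi, fi in points:
        if xi <= x:
            val = fi
        else:
            break
    return val


def clade_summary(stats: Sequence[PatternStats], clade: str) -> CladeBiasSummary:
    """Aggregate one pattern's per-genome stats over a clade.

    Genomes with undefined bias are dropped from the mean/median/ECDF;
    ``fraction_zero`` is the fraction of all input genomes whose
    observed count is zero (the "completely lack the motif" fraction).
    """
    if not stats:
        raise ValueError("no genomes")
    patterns = {s.pattern for s in stats}
    if len(patterns) > 1:
        raise ValueError(f"mixed patterns in clade summary: {sorted(patterns)}")
    defined = [s.bias for s in stats if s.defined]
    if not defined:
        raise ValueError(f"all biases undefined for clade {clade!r}")
    zero = sum(1 for s in stats if s.observed_count == 0)
    return CladeBiasSummary(
        clade=clade,
        pattern=next(iter(patterns)),
        n_genomes=len(stats),
        mean_bias=float(np.mean(defined)),
        median_bias=float(np.median(defined)),
        fraction_zero=zero / len(stats),
        ecdf_points=ecdf(defined),
    )


def clade_mean_bias(tables: Iterable[pd.DataFrame]) -> pd.Series:
    """Mean bias per pattern over a clade's per-genome bias tables.

    NaN (undefined) biases are dropped per pattern, matching the
    genome-dropping rule of :func:`clade_summary`.
    """
    frames = list(tables)
    if not frames:
        raise ValueError("no genome tables")
    cat = pd.concat(frames, ignore_index=True)
    return cat.groupby("pattern")["bias"].mean()


def rank_underrepresented(
    clade_means: Mapping[str, Mapping[str, float] | pd.Series],
    top_n: int = 20,
) -> list[tuple[str, float]]:
    """Rank patterns by the unweighted cross-clade mean of clade means,
    ascending (most underrepresented first); ties break lexicographically.
    """
    if not clade_means:
        raise ValueError("no clades")
    series = {clade: pd.Series(m, dtype=float) for clade, m in clade_means.items()}
    universe = None
    for s in series.values():
        idx = set(s.index)
        if universe is None:
            universe = idx
        elif idx != universe:
            raise ValueError("clades cover different pattern universes")
    df = pd.DataFrame(series)
    cross = df.mean(axis=1)
    ranked = sorted(cross.items(), key=lambda kv: (kv[1], kv[0]))
    return [(p, float(v)) for p, v in ranked[:top_n]]


def single_genome_report(
    proteome: Proteome, motifs: Sequence[str], k: int = 4
) -> pd.DataFrame:
    """Per-motif bias plus motif-containing protein counts for one genome.

    The worked-example view: for each motif, the frequency bias and the
    number of distinct proteins containing it.
    """
    rows = []
    for motif in motifs:
        st = frequency_bias(proteome, motif, k)
        n_prot = sum(1 for rec in proteome if motif in rec.sequence)
        rows.append(
            {
                "genome_id": proteome.genome_id,
                "motif": motif,
                "observed_count": st.observed_count,
                "total_windows": st.total_windows,
                "n_proteins": n_prot,
                "expected_freq": st.expected_freq,
                "bias": st.bias if st.defined else float("nan"),
            }
        )
    return pd.DataFrame(rows)
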