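"""Seeded simulation studies exercising the pipeline end to end.

Each function sets up a synthetic study with known ground truth, runs
the relevant pipeline stage, and returns the measured quantities; the
analysis drivers and the acceptance checks both call these.  Problem
sizes are chosen so each study resolves its effect well clear of
sampling noise while staying desk-scale.
"""

from __future__ import annotations

import tempfile

import numpy as np

from .io_formats import GeneFeature, read_gff3, read_protein_fasta
from .kmer_bias import (
    STANDARD_AA,
    bias_table,
    clade_mean_bias,
    composition,
    ecdf,
    ecdf_at,
    frequency_bias,
    rank_underrepresented,
)
from .motif_census import census, scan_motifs
from .synthetic_data import (
    GenomeSpec,
    MotifPlan,
    ProteomeSpec,
    generate_annotated_genome,
    generate_proteome,
)
from .uorf_enrichment import GenePair, enrichment_table, pair_uorfs, select_uorfs

#: Composition used for depletion-recovery studies: motif letters made
#: frequent so the background occurrence count resolves the planted factor.
SKEWED_COMPOSITION = {
    **{a: 0.0125 for a in STANDARD_AA},
    "R": 0.20, "A": 0.20, "P": 0.20, "L": 0.20,
}


def null_bias_study(
    seed: int, n_patterns: int = 20, n_proteins: int = 1500
) -> list[tuple[str, float, float]]:
    """Bias of random patterns in an unplanted iid proteome.

    The proteome (~4x10^5 windows) has no planted structure, so every
    pattern's bias should sit within sampling noise of 1.  Patterns are
    drawn letter-by-letter from the composition so their expected
    counts are resolvable.  Returns (pattern, bias, binomial SE of the
    bias) triples.
    """
    proteome, _ = generate_proteome(
        ProteomeSpec(
            genome_id="null", n_proteins=n_proteins,
            length_mu=5.7, length_sigma=0.3, seed=seed,
        )
    )
    rng = np.random.default_rng(seed + 1)
    comp = composition(proteome)
    out = []
    df = bias_table(proteome)
    df = df.set_index("pattern")
    total = int(df["total_windows"].iloc[0])
    for _ in range(n_patterns):
        pattern = "".join(rng.choice(list(STANDARD_AA), size=4, p=comp))
        row = df.loc[pattern]
        p_exp = float(row["expected_freq"])
        se = np.sqrt(p_exp * (1 - p_exp) / total) / p_exp
        out.append((pattern, float(row["bias"]), float(se)))
    return out


def depletion_recovery_study(seed: int, depletion: float, n_proteins: int = 3000) -> dict:
    """Plant a background depletion factor on RAPP and measure it back.

    Uses the motif-letter-rich composition and ~10^6 windows so the
    surviving occurrence count (hundreds) pins the bias to well under
    20% relative error.
    """
    proteome, truth = generate_proteome(
        ProteomeSpec(
            genome_id=f"depl{int(depletion * 100)}",
            n_proteins=n_proteins,
            length_mu=6.0, length_sigma=0.25,
            composition=SKEWED_COMPOSITION,
            motif_plan=[MotifPlan("RAPP", depletion=depletion)],
            seed=seed,
        )
    )
    st = frequency_bias(proteome, "RAPP")
    return {
        "planted_depletion": depletion,
        "measured_bias": st.bias,
        "observed_count": st.observed_count,
        "total_windows": st.total_windows,
        "relative_error": abs(st.bias - depletion) / depletion,
    }


def cterminal_placement_study(seed: int, n_proteins: int = 500) -> dict:
    """C-terminal vs uniform motif placement: distance-to-C ECDF dominance.

    Returns the two median distances and the number of deciles (of the
    uniform-placement distance distribution) at which the C-terminal
    ECDF dominates.
    """
    base = dict(n_proteins=n_proteins, length_mu=5.0, length_sigma=0.3)
    cterm, _ = generate_proteome(
        ProteomeSpec(
            genome_id="cterm", seed=seed,
            motif_plan=[MotifPlan("RAPP", p=1.0, placement="c_terminal", c_window=10)],
            **base,
        )
    )
    unif, _ = generate_proteome(
        ProteomeSpec(
            genome_id="unif", seed=seed + 1,
            motif_plan=[MotifPlan("RAPP", p=1.0, placement="uniform")],
            **base,
        )
    )
    d_ct = census(scan_motifs(cterm, ["RAPP"]))["RAPP"]["distances_per_protein"]
    d_un = census(scan_motifs(unif, ["RAPP"]))["RAPP"]["distances_per_protein"]
    e_ct, e_un = ecdf(d_ct), ecdf(d_un)
    deciles = np.quantile(d_un, np.arange(0.1, 1.0, 0.1))
    dominated = sum(1 for q in deciles if ecdf_at(e_ct, q) >= ecdf_at(e_un, q))
    return {
        "median_distance_cterminal": float(np.median(d_ct)),
        "median_distance_uniform": float(np.median(d_un)),
        "n_deciles": len(deciles),
        "n_deciles_dominated": int(dominated),
    }


def enrichment_recovery_study(
    seed: int,
    factor: float = 5.0,
    n_pairs: int = 500,
    n_groups: int = 20,
    n_replicates: int = 6,
    planted_group: str = "group 3 protein",
) -> dict:
    """Plant a fold-enrichment on one downstream group and recover it.

    A weight factor f on one of g equal-weight groups implies, after
    renormalization, a true proportion ratio r = (f/(g-1+f)) / (1/g) —
    the estimand of the fold-enrichment statistic.  Each replicate
    genome carries ``n_pairs`` uORFs per motif and runs the full
    parse-back pipeline (GFF3 + FASTA -> pairing -> filtering ->
    Fisher/BH); the fold estimate pools the 2x2 counts over
    replicates, while top-group rank and significance are taken from
    the first single replicate.
    """
    catalog = [(f"group {i} protein", 1.0) for i in range(n_groups)]
    pooled = {"a": 0, "b": 0, "c": 0, "d": 0}
    first_top = None
    for rep in range(n_replicates):
        spec = GenomeSpec(
            genome_id=f"enrich{rep}",
            n_pairs_per_motif={"RGPP": n_pairs, "AGPP": n_pairs},
            group_catalog=catalog,
            enrichment_plan={("RGPP", planted_group): factor},
            seed=seed + 7919 * rep,
        )
        genome = generate_annotated_genome(spec)
        with tempfile.TemporaryDirectory() as tmp:
            paths = genome.write(tmp)
            proteome = read_protein_fasta(paths["proteins"], genome.genome_id)
            features = read_gff3(paths["gff"])
        lengths = {p.protein_id: p.length for p in proteome}
        pairs = {}
        for motif in ("RGPP", "AGPP"):
            occ = scan_motifs(proteome, [motif])
            mapping = {o.protein_id: motif for o in occ}
            pairs[motif] = select_uorfs(pair_uorfs(features, mapping, lengths))
        results = enrichment_table(pairs["RGPP"], pairs["AGPP"])
        planted_key = planted_group.lower()
        planted_res = next(r for r in results if r.group_key == planted_key)
        for cell in ("a", "b", "c", "d"):
            pooled[cell] += getattr(planted_res, cell)
        if rep == 0:
            finite = [r for r in results if not r.infinite_fold]
            first_top = finite[0]
    true_fold = (factor / (n_groups - 1 + factor)) / (1 / n_groups)
    pooled_fold = (pooled["a"] / (pooled["a"] + pooled["b"])) / (
        pooled["c"] / (pooled["c"] + pooled["d"])
    )
    return {
        "planted_group": planted_group,
        "planted_factor": factor,
        "true_proportion_ratio": true_fold,
        "pooled_fold": pooled_fold,
        "relative_error": abs(pooled_fold - true_fold) / true_fold,
        "top_group": first_top.group_key,
        "top_fold": first_top.fold_enrichment,
        "top_p_adjusted": first_top.p_adjusted,
        "n_pairs_per_motif": n_pairs,
        "n_replicates": n_replicates,
    }


def null_enrichment_study(
    seed: int, n_replicates: int = 200, n_pairs: int = 100, n_groups: int = 20,
    threshold: float = 0.01,
) -> dict:
    """FDR sanity check: target and control drawn from the same multinomial.

    Returns the pooled fraction of (group, replicate) tests with
    adjusted p below the threshold, which FDR control should keep near
    or below that threshold.
    """
    rng = np.random.default_rng(seed)
    groups = [f"null group {i}" for i in range(n_groups)]
    n_sig = n_tests = 0
    for _ in range(n_replicates):
        pair_sets = []
        for motif in ("RGPP", "AGPP"):
            idx = rng.integers(0, n_groups, size=n_pairs)
            pair_sets.append(
                [_quick_pair(motif, groups[i]) for i in idx]
            )
        for r in enrichment_table(pair_sets[0], pair_sets[1], significance_threshold=threshold):
            n_tests += 1
            if r.p_adjusted < threshold:
                n_sig += 1
    frac = n_sig / n_tests
    se = np.sqrt(threshold * (1 - threshold) / n_tests)
    return {
        "fraction_significant": frac,
        "n_tests": n_tests,
        "threshold": threshold,
        "binomial_se": float(se),
    }


def _quick_pair(motif: str, group: str) -> GenePair:
    u = GeneFeature("u", "c", 100, 400, "+", "hypothetical protein", "u")
    d = GeneFeature("d", "c", 500, 900, "+", group, "d")
    return GenePair(u, d, motif, 100, 100)


def ranking_recovery_study(
    seed: int, n_clades: int = 3, genomes_per_clade: int = 3, n_proteins: int = 1200,
    depleted_pattern: str = "RGPP", depletion: float = 0.1,
) -> dict:
    """Scaled-down analog of the cross-clade underrepresentation heatmap.

    Genomes are drawn with a uniform amino-acid composition (so every
    one of the 160,000 patterns has the same, resolvable expected
    count) and the target pattern's background occurrences thinned to
    ``depletion`` in every genome.  The study checks that the planted
    pattern tops the cross-clade lowest-mean ranking.
    """
    uniform = {a: 0.05 for a in STANDARD_AA}
    clade_means = {}
    counter = 0
    for ci in range(n_clades):
        tables = []
        for gi in range(genomes_per_clade):
            counter += 1
            proteome, _ = generate_proteome(
                ProteomeSpec(
                    genome_id=f"c{ci}g{gi}", n_proteins=n_proteins,
                    length_mu=5.8, length_sigma=0.2,
                    composition=uniform,
                    motif_plan=[MotifPlan(depleted_pattern, depletion=depletion)],
                    seed=seed + 1000 * counter,
                )
            )
            proteome = proteome.with_clade(f"clade{ci}")
            tables.append(bias_table(proteome))
        clade_means[f"clade{ci}"] = clade_mean_bias(tables)
    ranked = rank_underrepresented(clade_means, top_n=20)
    top_pattern, top_mean = ranked[0]
    return {
        "depleted_pattern": depleted_pattern,
        "planted_depletion": depletion,
        "top_pattern": top_pattern,
        "top_cross_clade_mean": top_mean,
        "planted_rank": next(
            i + 1 for i, (p, _) in enumerate(ranked) if p == depleted_pattern
        ) if any(p == depleted_pattern for p, _ in ranked) else None,
        "n_genomes": n_clades * genomes_per_clade,
    }
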