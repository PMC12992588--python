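"""End-to-end orchestration of the two analyses.

``run_bias`` drives the frequency-bias stage over a directory of
protein FASTA files plus a taxonomy table (per-genome stats, per-clade
summaries and the cross-clade underrepresentation ranking);
``run_enrich`` drives the motif census and the uORF/downstream-gene
enrichment over paired FASTA/GFF3 genomes.  All outputs are TSV tables
with '#'-prefixed provenance comments, consumable by any plotting
layer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io_formats, kmer_bias, motif_census, uorf_enrichment

DEFAULT_MOTIF_PAIRS = (("RGPP", "AGPP"), ("RAPP", "AAPP"))


@dataclass
class RunConfig:
    """Shared knobs of the pipeline; defaults mirror the study design."""

    motifs: tuple[str, ...] = ("RAPP", "RGPP", "RAGP", "AAPP", "AGPP")
    k: int = 4
    length_cap: int = 300
    subsample_cap: int = 1000
    subsample_seed: int = kmer_bias.DEFAULT_SUBSAMPLE_SEED
    fisher_alternative: str = "two-sided"
    bh_threshold: float = 0.01
    max_gap: int | None = None
    allow_overlap: int = 0

    def to_text(self) -> str:
        lines = []
        for key, val in sorted(vars(self).items()):
            if isinstance(val, tuple):
                val = ",".join(str(v) for v in val)
            lines.append(f"{key} = {val}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in ("motifs",):
                kwargs[key] = tuple(v for v in val.split(",") if v)
            elif key in ("k", "length_cap", "subsample_cap", "subsample_seed", "allow_overlap"):
                kwargs[key] = int(val)
            elif key == "max_gap":
                kwargs[key] = None if val == "None" else int(val)
            elif key == "bh_threshold":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def _provenance(config: RunConfig, seed: int | None = None) -> str:
    line = f"# config_hash={config.digest()}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as out:
        out.write(header_comment)
        df.to_csv(out, sep="\t", index=False, float_format="%.10g")


def load_proteome_dir(
    fasta_dir: str | Path, taxonomy: Mapping[str, str] | None = None
) -> list[io_formats.Proteome]:
    """Read every *.faa / *.fasta in a directory; genome_id is the file
    stem; clade joined from the taxonomy when given (genomes without a
    taxonomy entry are skipped with a warning row in the log)."""
    fasta_dir = Path(fasta_dir)
    paths = sorted(
        p for p in fasta_dir.iterdir() if p.suffix in (".faa", ".fasta", ".fa")
    )
    if not paths:
        raise FileNotFoundError(f"no FASTA files in {fasta_dir}")
    proteomes = []
    for p in paths:
        genome_id = p.stem
        if taxonomy is not None and genome_id not in taxonomy:
            continue
        prot = io_formats.read_protein_fasta(p, genome_id)
        if taxonomy is not None:
            prot = prot.with_clade(taxonomy[genome_id])
        proteomes.append(prot)
    return proteomes


def run_bias(
    fasta_dir: str | Path,
    taxonomy_path: str | Path,
    outdir: str | Path,
    config: RunConfig | None = None,
    all_patterns: bool = False,
    top_n: int = 20,
) -> dict[str, Path]:
    """Frequency-bias stage: per-genome stats, clade summaries, ranking.

    With ``all_patterns`` the full 20^k pattern universe is scored per
    genome and the cross-clade lowest-mean ranking is emitted;
    otherwise only the configured motifs are scored.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    taxonomy = io_formats.read_taxonomy(taxonomy_path)
    proteomes = load_proteome_dir(fasta_dir, taxonomy)
    if not proteomes:
        raise ValueError("no proteome has a taxonomy entry")
    sampled = kmer_bias.subsample_genomes(
        [p.genome_id for p in proteomes], taxonomy,
        cap=config.subsample_cap, seed=config.subsample_seed,
    )
    keep = {g for members in sampled.values() for g in members}
    proteomes = [p for p in proteomes if p.genome_id in keep]

    patterns = None if all_patterns else list(config.motifs)
    tables = {p.genome_id: kmer_bias.bias_table(p, patterns, k=config.k) for p in proteomes}
    per_genome = pd.concat(tables.values(), ignore_index=True)

    prov = _provenance(config, config.subsample_seed)
    paths = {}
    if not all_patterns:
        paths["per_genome"] = outdir / "pattern_stats.tsv"
        _write_tsv(per_genome, paths["per_genome"], prov)

    clades = sorted({p.clade for p in proteomes})
    summaries, ecdf_rows = [], []
    motif_list = list(config.motifs)
    for clade in clades:
        members = [p for p in proteomes if p.clade == clade]
        for motif in motif_list:
            stats = [kmer_bias.frequency_bias(p, motif, config.k) for p in members]
            try:
                s = kmer_bias.clade_summary(stats, clade)
            except ValueError:
                continue
            summaries.append(
                {
                    "clade": clade, "pattern": motif, "n_genomes": s.n_genomes,
                    "mean_bias": s.mean_bias, "median_bias": s.median_bias,
                    "fraction_zero": s.fraction_zero,
                }
            )
            for x, f in s.ecdf_points:
                ecdf_rows.append({"clade": clade, "pattern": motif, "bias": x, "cum_fraction": f})
    paths["clade_summary"] = outdir / "clade_summary.tsv"
    _write_tsv(pd.DataFrame(summaries), paths["clade_summary"], prov)
    paths["ecdf"] = outdir / "ecdf_points.tsv"
    _write_tsv(pd.DataFrame(ecdf_rows), paths["ecdf"], prov)

    if all_patterns:
        clade_means = {}
        for clade in clades:
            clade_means[clade] = kmer_bias.clade_mean_bias(
                tables[p.genome_id] for p in proteomes if p.clade == clade
            )
        ranking = kmer_bias.rank_underrepresented(clade_means, top_n=top_n)
        rank_df = pd.DataFrame(ranking, columns=["pattern", "cross_clade_mean_bias"])
        for clade in clades:
            rank_df[clade] = [clade_means[clade][p] for p in rank_df["pattern"]]
        paths["ranking"] = outdir / "underrepresentation_ranking.tsv"
        _write_tsv(rank_df, paths["ranking"], prov)
    return paths


def run_enrich(
    genomes: Sequence[tuple[str | Path, str | Path]],
    outdir: str | Path,
    config: RunConfig | None = None,
    motif_pairs: Sequence[tuple[str, str]] = DEFAULT_MOTIF_PAIRS,
) -> dict[str, Path]:
    """Census + enrichment stage over (protein FASTA, GFF3) genome pairs.

    Scans for all configured motifs, pairs small motif-bearing uORFs
    with their same-strand downstream genes, pools pairs across
    genomes, and tests per-annotation-group enrichment for each
    (target, control) motif pair.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_occurrences: list[motif_census.MotifOccurrence] = []
    pairs_by_motif: dict[str, list[uorf_enrichment.GenePair]] = {m: [] for m in config.motifs}
    for fasta_path, gff_path in genomes:
        genome_id = Path(fasta_path).stem
        proteome = io_formats.read_protein_fasta(fasta_path, genome_id)
        features = io_formats.read_gff3(gff_path)
        fasta_ids = {p.protein_id for p in proteome}
        unmatched = sorted(
            f.protein_id for f in features
            if f.protein_id is not None and f.protein_id not in fasta_ids
        )
        if unmatched:
            raise ValueError(
                f"{gff_path}: protein_ids missing from {fasta_path}: {', '.join(unmatched)}"
            )
        lengths = {p.protein_id: p.length for p in proteome}
        occurrences = motif_census.scan_motifs(proteome, config.motifs)
        all_occurrences.extend(occurrences)
        by_motif: dict[str, dict[str, str]] = {}
        for o in occurrences:
            by_motif.setdefault(o.motif, {})[o.protein_id] = o.motif
        for motif, mapping in by_motif.items():
            raw = uorf_enrichment.pair_uorfs(
                features, mapping, lengths,
                max_gap=config.max_gap, allow_overlap=config.allow_overlap,
            )
            pairs_by_motif[motif].extend(
                uorf_enrichment.select_uorfs(raw, length_cap=config.length_cap)
            )

    prov = _provenance(config)
    census_result = motif_census.census(all_occurrences, config.length_cap)
    paths = {"census": Path(outdir) / "census.tsv"}
    _write_tsv(motif_census.census_frame(census_result), paths["census"], prov)
    paths["occurrences"] = Path(outdir) / "occurrences.tsv"
    _write_tsv(motif_census.occurrences_frame(all_occurrences), paths["occurrences"], prov)

    pair_rows = []
    for motif, pairs in pairs_by_motif.items():
        for pr in pairs:
            pair_rows.append(
                {
                    "motif": motif,
                    "uorf_protein_id": pr.uorf.protein_id,
                    "downstream_protein_id": pr.downstream.protein_id,
                    "group": pr.group_key,
                    "intergenic_distance": pr.intergenic_distance,
                    "uorf_length": pr.uorf_protein_length,
                }
            )
    paths["pairs"] = Path(outdir) / "pairs.tsv"
    _write_tsv(pd.DataFrame(pair_rows), paths["pairs"], prov)

    for target, control in motif_pairs:
        if not pairs_by_motif.get(target) or not pairs_by_motif.get(control):
            continue
        results = uorf_enrichment.enrichment_table(
            pairs_by_motif[target], pairs_by_motif[control],
            alternative=config.fisher_alternative,
            significance_threshold=config.bh_threshold,
        )
        key = f"enrichment_{target}_vs_{control}"
        paths[key] = Path(outdir) / f"{key}.tsv"
        _write_tsv(uorf_enrichment.enrichment_frame(results), paths[key], prov)
    return paths
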