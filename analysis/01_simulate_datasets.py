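#!/usr/bin/env python
"""Generate the synthetic study datasets used by the downstream drivers.

Builds, under scratch/synthetic/:
  * a 9-genome, 3-clade proteome set with RGPP background occurrences
    thinned to 0.1 in every genome (uniform composition so all 160,000
    tetrapeptides share one expected frequency), plus its taxonomy TSV;
  * one annotated toy genome with 500 RGPP and 500 AGPP uORF pairs and
    a 5x weight enrichment planted on "group 3 protein".

Run:  python analysis/01_simulate_datasets.py [--seed 2029]
"""

import argparse
from pathlib import Path

from rappmotif.io_formats import write_protein_fasta, write_taxonomy
from rappmotif.kmer_bias import STANDARD_AA
from rappmotif.synthetic_data import (
    GenomeSpec,
    MotifPlan,
    ProteomeSpec,
    generate_annotated_genome,
    generate_proteome,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2029)
    ap.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "synthetic")
    args = ap.parse_args()
    outdir = args.outdir
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)

    uniform = {a: 0.05 for a in STANDARD_AA}
    taxonomy = {}
    counter = 0
    for ci in range(3):
        for gi in range(3):
            counter += 1
            genome_id = f"c{ci}g{gi}"
            proteome, truth = generate_proteome(
                ProteomeSpec(
                    genome_id=genome_id, n_proteins=1200,
                    length_mu=5.8, length_sigma=0.2, composition=uniform,
                    motif_plan=[MotifPlan("RGPP", depletion=0.1)],
                    seed=args.seed + 1000 * counter,
                )
            )
            write_protein_fasta(proteome, outdir / "proteomes" / f"{genome_id}.faa")
            taxonomy[genome_id] = f"clade{ci}"
            print(
                f"{genome_id}: {len(proteome)} proteins, "
                f"{truth['final_occurrence_counts']['RGPP']} RGPP occurrences left after thinning"
            )
    write_taxonomy(taxonomy, outdir / "taxonomy.tsv")

    genome = generate_annotated_genome(
        GenomeSpec(
            genome_id="toy",
            n_pairs_per_motif={"RGPP": 500, "AGPP": 500},
            group_catalog=[(f"group {i} protein", 1.0) for i in range(20)],
            enrichment_plan={("RGPP", "group 3 protein"): 5.0},
            seed=args.seed,
        )
    )
    paths = genome.write(outdir / "toygenome")
    n_g3 = sum(
        1 for p in genome.ground_truth["pairs"]
        if p["motif"] == "RGPP" and p["group"] == "group 3 protein"
    )
    print(f"toy genome: 1000 uORF pairs; {n_g3} RGPP pairs hit the enriched group")
    print(f"wrote {outdir}")


if __name__ == "__main__":
    main()
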