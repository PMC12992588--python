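"""Synthetic proteomes and annotated toy genomes with known ground truth.

Every pipeline stage is testable without downloads: proteomes are drawn
iid from a specified 20-letter composition with lognormal lengths,
motifs are planted at a controlled per-protein rate with a controllable
C-terminal positional bias, background motif occurrences are thinned to
an exact target depletion factor, and toy genomes carry uORF /
downstream-gene pairs whose annotation groups follow a multinomial with
planted per-(motif, group) enrichment factors.

What these generators emulate — and what they do not (no codon usage,
no GC structure, no phylogenetic correlation between genomes) — is laid
out in the package's methods notes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ProteinRecord, Proteome, write_protein_fasta
from .kmer_bias import STANDARD_AA
from .motif_census import find_occurrences

#: A mildly skewed, realistic-looking default amino-acid composition
#: (frequent A/L/G/E, rare C/W), normalized at import time.
DEFAULT_COMPOSITION = {
    "A": 0.095, "C": 0.012, "D": 0.054, "E": 0.060, "F": 0.040,
    "G": 0.074, "H": 0.022, "I": 0.058, "K": 0.053, "L": 0.102,
    "M": 0.023, "N": 0.041, "P": 0.046, "Q": 0.038, "R": 0.055,
    "S": 0.062, "T": 0.054, "V": 0.069, "W": 0.013, "Y": 0.029,
}
_total = sum(DEFAULT_COMPOSITION.values())
DEFAULT_COMPOSITION = {a: v / _total for a, v in DEFAULT_COMPOSITION.items()}


@dataclass(frozen=True)
class MotifPlan:
    """Planting/depletion instructions for one motif.

    ``p`` is the per-protein planting probability; ``placement`` is
    "uniform" or "c_terminal"; ``c_window`` bounds the distance of the
    planted motif's last residue from the C-terminus when placement is
    C-terminal; ``depletion`` thins *background* (non-planted)
    occurrences so each survives with exactly that probability.
    """

    motif: str
    p: float = 0.0
    placement: str = "uniform"
    c_window: int = 10
    depletion: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("planting probability must be in [0, 1]")
        if not (0.0 < self.depletion <= 1.0):
            raise ValueError("depletion factor must be in (0, 1]")
        if self.placement not in ("uniform", "c_terminal"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class ProteomeSpec:
    genome_id: str = "synthetic"
    n_proteins: int = 100
    length_mu: float = 5.5      # lognormal log-scale: median length exp(5.5) ~ 245
    length_sigma: float = 0.45
    length_min: int = 50
    length_max: int = 2000
    composition: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    motif_plan: Sequence[MotifPlan] = ()
    seed: int = 0


def _comp_vector(composition: Mapping[str, float]) -> np.ndarray:
    vec = np.array([composition.get(a, 0.0) for a in STANDARD_AA], dtype=float)
    if vec.min() < 0 or vec.sum() <= 0:
        raise ValueError("invalid composition")
    return vec / vec.sum()


def _truncated_lognormal_lengths(
    rng: np.random.Generator, n: int, mu: float, sigma: float, lo: int, hi: int
) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.lognormal(mu, sigma, size=2 * (n - filled))).astype(np.int64)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_proteome(spec: ProteomeSpec) -> tuple[Proteome, dict]:
    """Draw a proteome from the spec; returns it plus a ground-truth record.

    Residues are iid from the composition; planted motifs overwrite
    residues at the chosen position; background occurrences of each
    planned motif are then thinned: with probability 1 - d one window
    residue is resampled from the composition *conditioned on differing
    from the motif letter at that position*, so each background
    occurrence survives with probability exactly d.
    """
    rng = np.random.default_rng(spec.seed)
    comp = _comp_vector(spec.composition)
    letters = np.array(list(STANDARD_AA))
    lengths = _truncated_lognormal_lengths(
        rng, spec.n_proteins, spec.length_mu, spec.length_sigma,
        spec.length_min, spec.length_max,
    )
    for plan in spec.motif_plan:
        if len(plan.motif) > spec.length_min:
            raise ValueError(f"motif {plan.motif!r} longer than minimum protein length")

    pool = rng.choice(letters, size=int(lengths.sum()), p=comp)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    planted_counts = {plan.motif: 0 for plan in spec.motif_plan}
    planted_positions: list[dict[str, set[int]]] = []
    seqs: list[np.ndarray] = []
    for i, L in enumerate(lengths):
        seq = pool[offsets[i] : offsets[i + 1]].copy()
        planted: dict[str, set[int]] = {}
        for plan in spec.motif_plan:
            m = len(plan.motif)
            if plan.p > 0 and rng.random() < plan.p:
                if plan.placement == "c_terminal":
                    max_dist = min(plan.c_window - 1, L - m)
                    dist = int(rng.integers(0, max_dist + 1))
                    start0 = L - m - dist
                else:
                    start0 = int(rng.integers(0, L - m + 1))
                seq[start0 : start0 + m] = list(plan.motif)
                planted.setdefault(plan.motif, set()).add(start0)
                planted_counts[plan.motif] += 1
        planted_positions.append(planted)
        seqs.append(seq)

    # background thinning
    for i, seq in enumerate(seqs):
        s = "".join(seq)
        for plan in spec.motif_plan:
            if plan.depletion >= 1.0:
                continue
            m = plan.motif
            keep = planted_positions[i].get(m, set())
            for start1 in find_occurrences(s, m):
                start0 = start1 - 1
                if start0 in keep:
                    continue
                if rng.random() < plan.depletion:
                    continue
                j = int(rng.integers(0, len(m)))
                forbidden = m[j]
                cond = comp.copy()
                cond[STANDARD_AA.index(forbidden)] = 0.0
                cond = cond / cond.sum()
                seq[start0 + j] = rng.choice(letters, p=cond)
            s = "".join(seq)

    proteins = [
        ProteinRecord(f"{spec.genome_id}_p{i + 1:05d}", spec.genome_id, "".join(seq))
        for i, seq in enumerate(seqs)
    ]
    proteome = Proteome(genome_id=spec.genome_id, clade="", proteins=proteins)
    final_counts = {
        plan.motif: sum(len(find_occurrences(p.sequence, plan.motif)) for p in proteins)
        for plan in spec.motif_plan
    }
    truth = {
        "composition": {a: float(f) for a, f in zip(STANDARD_AA, comp)},
        "lengths": lengths.tolist(),
        "planted_counts": planted_counts,
        "final_occurrence_counts": final_counts,
        "seed": spec.seed,
    }
    return proteome, truth


@dataclass
class GenomeSpec:
    """Recipe for an annotated toy genome with uORF/downstream pairs."""

    genome_id: str = "toygenome"
    n_pairs_per_motif: Mapping[str, int] = field(
        default_factory=lambda: {"RGPP": 50, "AGPP": 50}
    )
    group_catalog: Sequence[tuple[str, float]] = field(
        default_factory=lambda: [(f"group {i} protein", 1.0) for i in range(10)]
    )
    enrichment_plan: Mapping[tuple[str, str], float] = field(default_factory=dict)
    max_gap: int = 500
    n_decoys: int = 20
    seed: int = 0


@dataclass
class SyntheticGenome:
    genome_id: str
    contig_id: str
    contig_sequence: str
    gff_lines: list[str]
    proteome: Proteome
    ground_truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / f"{self.genome_id}.fna",
            "gff": outdir / f"{self.genome_id}.gff3",
            "proteins": outdir / f"{self.genome_id}.faa",
            "truth": outdir / f"{self.genome_id}.truth.json",
        }
        with open(paths["genome"], "w") as out:
            out.write(f">{self.contig_id}\n")
            seq = self.contig_sequence
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")
        with open(paths["gff"], "w") as out:
            out.write("##gff-version 3\n")
            out.write("\n".join(self.gff_lines) + "\n")
        write_protein_fasta(self.proteome, paths["proteins"])
        with open(paths["truth"], "w") as out:
            json.dump(self.ground_truth, out, indent=1, sort_keys=True)
        return paths


def _random_protein(rng: np.random.Generator, comp: np.ndarray, length: int) -> str:
    letters = np.array(list(STANDARD_AA))
    return "".join(rng.choice(letters, size=length, p=comp))


def _plant_cterminal(seq: str, motif: str, rng: np.random.Generator, window: int = 10) -> str:
    L, m = len(seq), len(motif)
    dist = int(rng.integers(0, min(window, L - m + 1)))
    start0 = L - m - dist
    return seq[:start0] + motif + seq[start0 + m :]


def generate_annotated_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Build a toy genome whose GFF3 contains planted uORF/downstream pairs.

    Each uORF is a small (<300 aa) hypothetical protein carrying its
    motif near the C-terminus; its same-strand neighbor in translation
    direction gets an annotation drawn from the group multinomial with
    the pair's (motif, group) enrichment factor applied.  Decoy genes
    sit on the opposite strand between pair blocks, so parse-back with
    the downstream-pairing stage recovers every planted pair.
    """
    rng = np.random.default_rng(spec.seed)
    comp = _comp_vector(DEFAULT_COMPOSITION)
    groups = [g for g, _ in spec.group_catalog]
    base_w = np.array([w for _, w in spec.group_catalog], dtype=float)
    if base_w.min() < 0:
        raise ValueError("group weights must be >= 0")

    jobs: list[str] = []
    for motif in sorted(spec.n_pairs_per_motif):
        jobs += [motif] * spec.n_pairs_per_motif[motif]
    rng.shuffle(jobs)

    contig_id = f"{spec.genome_id}_c1"
    gff: list[str] = []
    proteins: list[ProteinRecord] = []
    truth_pairs: list[dict] = []
    cursor = 1
    pid_counter = 0

    def next_pid() -> str:
        nonlocal pid_counter
        pid_counter += 1
        return f"{spec.genome_id}_p{pid_counter:05d}"

    def gff_line(pid: str, start: int, end: int, strand: str, product: str) -> str:
        return (
            f"{contig_id}\tsynthetic\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
            f"ID={pid};protein_id={pid};product={product}"
        )

    decoy_every = max(1, len(jobs) // max(spec.n_decoys, 1)) if spec.n_decoys else 0

    for j, motif in enumerate(jobs):
        strand = "+" if rng.random() < 0.5 else "-"
        uorf_len = int(rng.integers(60, 250))
        down_len = int(rng.integers(100, 400))
        gap = int(rng.integers(0, spec.max_gap + 1))
        w = base_w.copy()
        for gi, g in enumerate(groups):
            w[gi] *= spec.enrichment_plan.get((motif, g), 1.0)
        group = groups[int(rng.choice(len(groups), p=w / w.sum()))]

        uorf_seq = _plant_cterminal(_random_protein(rng, comp, uorf_len), motif, rng)
        down_seq = _random_protein(rng, comp, down_len)
        uorf_pid, down_pid = next_pid(), next_pid()
        uorf_nt_len = 3 * (uorf_len + 1)
        down_nt_len = 3 * (down_len + 1)

        if strand == "+":
            uorf_start = cursor
            uorf_end = uorf_start + uorf_nt_len - 1
            down_start = uorf_end + 1 + gap
            down_end = down_start + down_nt_len - 1
            block_end = down_end
        else:
            down_start = cursor
            down_end = down_start + down_nt_len - 1
            uorf_start = down_end + 1 + gap
            uorf_end = uorf_start + uorf_nt_len - 1
            block_end = uorf_end
        gff.append(gff_line(uorf_pid, uorf_start, uorf_end, strand, "hypothetical protein"))
        gff.append(gff_line(down_pid, down_start, down_end, strand, group))
        proteins.append(ProteinRecord(uorf_pid, spec.genome_id, uorf_seq))
        proteins.append(ProteinRecord(down_pid, spec.genome_id, down_seq))
        truth_pairs.append(
            {
                "uorf_protein_id": uorf_pid,
                "downstream_protein_id": down_pid,
                "motif": motif,
                "group": group,
                "strand": strand,
                "intergenic_distance": gap + 1,
            }
        )
        cursor = block_end + 1 + int(rng.integers(200, 400))

        if decoy_every and (j + 1) % decoy_every == 0:
            decoy_len = int(rng.integers(80, 200))
            decoy_pid = next_pid()
            decoy_strand = "-" if strand == "+" else "+"
            decoy_start = cursor
            decoy_end = decoy_start + 3 * (decoy_len + 1) - 1
            gff.append(gff_line(decoy_pid, decoy_start, decoy_end, decoy_strand, "decoy protein"))
            proteins.append(
                ProteinRecord(decoy_pid, spec.genome_id, _random_protein(rng, comp, decoy_len))
            )
            cursor = decoy_end + 1 + int(rng.integers(200, 400))

    contig_len = cursor + 100
    contig = rng.integers(0, 4, size=contig_len)
    contig_sequence = "".join("ACGT"[i] for i in contig)

    truth = {
        "pairs": truth_pairs,
        "groups": groups,
        "base_weights": base_w.tolist(),
        "enrichment_plan": {f"{m}|{g}": f for (m, g), f in spec.enrichment_plan.items()},
        "seed": spec.seed,
    }
    return SyntheticGenome(
        genome_id=spec.genome_id,
        contig_id=contig_id,
        contig_sequence=contig_sequence,
        gff_lines=gff,
        proteome=Proteome(spec.genome_id, "", proteins),
        ground_truth=truth,
    )
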