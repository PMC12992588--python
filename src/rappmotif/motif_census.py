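"""Motif census: occurrences, C-terminal positional bias, localization.

Scans proteomes for tetrapeptide motifs (RAPP, RGPP, and the AAPP/AGPP
controls), applies the small-protein filter (<300 aa, the size class
where regulatory arrest peptides live), computes distance-to-C-terminus
distributions, and classifies each protein as secretory (SP),
transmembrane (TM) or cytosolic (CP) through a pluggable predictor.

The default predictor is a documented Kyte-Doolittle hydropathy
heuristic; an adapter for DeepTMHMM's 3-line output format is provided
for users who run that tool externally.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ProteinRecord, Proteome
from .kmer_bias import ecdf

DEFAULT_MOTIFS = ("RAPP", "RGPP", "RAGP", "AAPP", "AGPP")
DEFAULT_LENGTH_CAP = 300

# Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPATHY_WINDOW = 19
HYDROPATHY_THRESHOLD = 1.6
SIGNAL_REGION_END = 35


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif hit inside a protein; 1-based inclusive coordinates.

    ``distance_to_C`` is protein_length - end: 0 when the motif's last
    residue is the protein's last residue.
    """

    protein_id: str
    genome_id: str
    motif: str
    start: int
    end: int
    protein_length: int
    localization: str | None = None

    @property
    def distance_to_C(self) -> int:
        return self.protein_length - self.end


@dataclass
class LocalizationCall:
    """SP/TM/CP call with its predicted segments as evidence."""

    klass: str
    evidence: list[tuple[int, int, str]] = field(default_factory=list)
    warning: str | None = None


def find_occurrences(sequence: str, motif: str) -> list[int]:
    """1-based start positions of every (possibly overlapping) hit."""
    starts = []
    i = sequence.find(motif)
    while i != -1:
        starts.append(i + 1)
        i = sequence.find(motif, i + 1)
    return starts


def scan_motifs(
    proteome: Proteome, motifs: Sequence[str]
) -> list[MotifOccurrence]:
    """All occurrences of all motifs, sorted by (genome, protein, start)."""
    if not motifs:
        raise ValueError("no motifs given")
    occ: list[MotifOccurrence] = []
    for rec in proteome:
        for motif in motifs:
            for start in find_occurrences(rec.sequence, motif):
                occ.append(
                    MotifOccurrence(
                        protein_id=rec.protein_id,
                        genome_id=rec.genome_id,
                        motif=motif,
                        start=start,
                        end=start + len(motif) - 1,
                        protein_length=rec.length,
                    )
                )
    occ.sort(key=lambda o: (o.genome_id, o.protein_id, o.start))
    return occ


def census(
    occurrences: Sequence[MotifOccurrence],
    length_cap: int = DEFAULT_LENGTH_CAP,
) -> dict[str, dict]:
    """Per-motif protein counts, length and distance-to-C distributions.

    A protein counts once per motif regardless of how many times the
    motif occurs in it.  The small-protein subset uses strict
    ``length < length_cap``.  Per-protein distance summaries use the
    C-terminal-most occurrence; the full per-occurrence list is also
    retained for positional plots.
    """
    by_motif: dict[str, list[MotifOccurrence]] = defaultdict(list)
    for o in occurrences:
        by_motif[o.motif].append(o)
    out: dict[str, dict] = {}
    for motif, occs in by_motif.items():
        per_protein: dict[tuple[str, str], MotifOccurrence] = {}
        for o in occs:
            key = (o.genome_id, o.protein_id)
            best = per_protein.get(key)
            if best is None or o.distance_to_C < best.distance_to_C:
                per_protein[key] = o
        proteins = list(per_protein.values())
        small = [o for o in proteins if o.protein_length < length_cap]
        out[motif] = {
            "n_occurrences": len(occs),
            "n_proteins": len(proteins),
            "n_small_proteins": len(small),
            "protein_lengths": sorted(o.protein_length for o in proteins),
            "distances_per_protein": sorted(o.distance_to_C for o in proteins),
            "distances_small": sorted(o.distance_to_C for o in small),
            "distance_ecdf": ecdf([o.distance_to_C for o in proteins])
            if proteins
            else [],
            "occurrences": occs,
        }
    return out


def census_frame(census_result: Mapping[str, dict]) -> pd.DataFrame:
    rows = [
        {
            "motif": motif,
            "n_occurrences": d["n_occurrences"],
            "n_proteins": d["n_proteins"],
            "n_small_proteins": d["n_small_proteins"],
            "median_length": float(np.median(d["protein_lengths"])) if d["protein_lengths"] else float("nan"),
            "median_distance_to_C": float(np.median(d["distances_per_protein"])) if d["distances_per_protein"] else float("nan"),
        }
        for motif, d in sorted(census_result.items())
    ]
    return pd.DataFrame(rows)


def _hydropathy_segments(sequence: str, window: int, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of residues whose centered length-`window` mean
    hydropathy is >= threshold (the usual Kyte-Doolittle plot
    convention); 1-based inclusive residue coordinates."""
    n = len(sequence)
    half = window // 2
    scores = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in sequence])
    marked = []
    for center in range(half, n - half):
        if scores[center - half : center + half + 1].mean() >= threshold:
            marked.append(center + 1)
    segments: list[tuple[int, int]] = []
    for pos in marked:
        if segments and pos == segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], pos)
        else:
            segments.append((pos, pos))
    return segments


def hydropathy_predictor(protein: ProteinRecord) -> LocalizationCall:
    """Default SP/TM/CP heuristic from Kyte-Doolittle hydropathy.

    Residues whose centered 19-residue window has mean hydropathy
    >= 1.6 form membrane-like ("tm") segments.  A tm-like segment
    lying fully within residues 1-35
    that is preceded by at least one positively charged residue (K/R)
    is reclassified as a signal peptide H-region ("signal").  Class:
    SP if a signal segment exists and no tm segment remains after
    residue 35; TM if any tm segment extends past residue 35; else CP.
    Proteins shorter than the window are CP with a warning flag.
    """
    seq = protein.sequence
    if len(seq) < HYDROPATHY_WINDOW:
        return LocalizationCall("CP", [], warning="shorter than hydropathy window")
    segments = _hydropathy_segments(seq, HYDROPATHY_WINDOW, HYDROPATHY_THRESHOLD)
    evidence: list[tuple[int, int, str]] = []
    has_signal = False
    has_tm_after = False
    for s, e in segments:
        if e <= SIGNAL_REGION_END and any(c in "KR" for c in seq[: s - 1]):
            evidence.append((s, e, "signal"))
            has_signal = True
        else:
            evidence.append((s, e, "tm"))
            if e > SIGNAL_REGION_END:
                has_tm_after = True
    if has_tm_after:
        return LocalizationCall("TM", evidence)
    if has_signal:
        return LocalizationCall("SP", evidence)
    return LocalizationCall("CP", evidence)


def classify_localization(
    protein: ProteinRecord,
    predictor: Callable[[ProteinRecord], LocalizationCall] = hydropathy_predictor,
) -> LocalizationCall:
    """Classify a protein as SP/TM/CP via the given predictor."""
    call = predictor(protein)
    if call.klass not in ("SP", "TM", "CP"):
        raise ValueError(f"predictor returned unknown class {call.klass!r}")
    return call


def read_deeptmhmm_3line(path: str | Path) -> dict[str, LocalizationCall]:
    """Adapter for DeepTMHMM's 3-line output (run externally).

    Each record is a ``>id | TYPE`` header, the sequence, and a
    per-residue topology string (S = signal, M = membrane).  Types map
    onto the three classes used here: SP -> SP; TM and SP+TM -> TM;
    everything else (GLOB, BETA) -> CP.
    """
    calls: dict[str, LocalizationCall] = {}
    lines = [l.rstrip("\n") for l in open(path) if l.strip()]
    for i in range(0, len(lines), 3):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"{path}: expected header at record {i // 3 + 1}")
        name_part, _, type_part = header[1:].partition("|")
        pid = name_part.strip()
        pred_type = type_part.strip().upper()
        topo = lines[i + 2] if i + 2 < len(lines) else ""
        evidence: list[tuple[int, int, str]] = []
        for kind, char in (("signal", "S"), ("tm", "M")):
            start = None
            for pos, c in enumerate(topo + " ", start=1):
                if c == char and start is None:
                    start = pos
                elif c != char and start is not None:
                    evidence.append((start, pos - 1, kind))
                    start = None
        if pred_type == "SP":
            klass = "SP"
        elif pred_type in ("TM", "SP+TM"):
            klass = "TM"
        else:
            klass = "CP"
        calls[pid] = LocalizationCall(klass, sorted(evidence))
    return calls


def occurrences_frame(
    occurrences: Sequence[MotifOccurrence],
    localization: Mapping[str, LocalizationCall] | None = None,
) -> pd.DataFrame:
    """Flat per-occurrence table (the TSV surface of this module)."""
    rows = []
    for o in occurrences:
        loc = None
        if localization is not None and o.protein_id in localization:
            loc = localization[o.protein_id].klass
        rows.append(
            {
                "genome_id": o.genome_id,
                "protein_id": o.protein_id,
                "motif": o.motif,
                "start": o.start,
                "end": o.end,
                "protein_length": o.protein_length,
                "distance_to_C": o.distance_to_C,
                "localization": loc,
            }
        )
    return pd.DataFrame(rows)
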