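"""Truncated-isoform prediction for loss-of-function variants.

An N-terminal truncating variant can be rescued by translation re-initiation
at a downstream in-frame ATG with a favourable Kozak context
((gcc)gccRccAUGG: the purine at -3 and the G at +4 dominate initiation
strength). This module scans a coding sequence for such alternative start
sites, reports which annotated protein features a truncation removes, and
predicts fusion-protein masses for gel-scale comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from Bio.SeqUtils import molecular_weight

from .variants import Consequence, ProteinConsequence

__all__ = [
    "KozakStrength",
    "KozakSite",
    "TruncationReport",
    "kozak_scan",
    "kozak_context",
    "truncation_report",
    "predicted_mass",
]

_PURINES = frozenset("AG")


class KozakStrength(str, Enum):
    """Initiation-context strength: purine at -3 and/or G at +4."""

    strong = "strong"      # purine at -3 AND G at +4
    adequate = "adequate"  # exactly one of the two
    weak = "weak"          # neither

    @property
    def rank(self) -> int:
        return {"strong": 2, "adequate": 1, "weak": 0}[self.value]


@dataclass(frozen=True)
class KozakSite:
    """An in-frame downstream ATG with its initiation context.

    ``nt_position`` is the 1-based CDS coordinate of the A of ATG;
    ``context`` covers positions -6..+4 (10 characters, '-' where the
    sequence does not extend that far; missing positions count as
    mismatches).
    """

    nt_position: int
    codon_index: int
    strength: KozakStrength
    context: str
    in_frame: bool
    consensus_score: float


# Kozak consensus at positions -6..-1 and +4 (ATG occupies +1..+3).
_CONSENSUS_FLANK = {-6: "G", -5: "C", -4: "C", -3: "R", -2: "C", -1: "C", 4: "G"}


def kozak_context(cds: str, nt_position: int) -> tuple[str, KozakStrength, float]:
    """Context string, strength and consensus similarity for an ATG at
    ``nt_position`` (1-based, the A of ATG)."""
    i = nt_position - 1  # 0-based index of A
    chars = []
    for off in range(-6, 5):
        if off == 0:
            continue
        j = i + off if off < 0 else i + off - 1  # +1..+3 are the ATG itself
        chars.append(cds[j] if 0 <= j < len(cds) else "-")
    context = "".join(chars)  # 10 chars: 6 upstream, ATG, +4
    minus3 = context[3]
    plus4 = context[9]
    has_r = minus3 in _PURINES
    has_g = plus4 == "G"
    if has_r and has_g:
        strength = KozakStrength.strong
    elif has_r or has_g:
        strength = KozakStrength.adequate
    else:
        strength = KozakStrength.weak
    matches = 0
    for off, want in _CONSENSUS_FLANK.items():
        got = context[off + 6] if off < 0 else context[9]
        if want == "R":
            matches += got in _PURINES
        else:
            matches += got == want
    score = matches / len(_CONSENSUS_FLANK)
    return context, strength, score


def kozak_scan(
    cds: str,
    min_codon: int = 2,
    stringency: KozakStrength | str = KozakStrength.strong,
) -> list[KozakSite]:
    """Find in-frame downstream ATG codons whose context meets ``stringency``.

    Only in-frame starts are reported: an out-of-frame ATG cannot produce
    the N-terminally truncated isoform of the reference protein. Sites are
    ordered by position; ``min_codon`` (>= 2) skips the annotated start and
    any codons upstream of the variant under study. Relaxing stringency
    (strong -> adequate -> weak) yields a superset of sites.
    """
    stringency = KozakStrength(stringency)
    cds = cds.upper()
    bad = [i for i, b in enumerate(cds) if b not in "ACGT"]
    if bad:
        raise ValueError(f"non-ACGT character {cds[bad[0]]!r} at offset {bad[0]}")
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if min_codon < 2:
        raise ValueError("min_codon must be >= 2 (codon 1 is the annotated start)")
    if not cds.startswith("ATG"):
        warnings.warn("CDS does not begin with ATG; scanning anyway", stacklevel=2)
    if len(cds) % 3:
        warnings.warn("CDS length is not a multiple of 3", stacklevel=2)

    sites = []
    for nt in range(1 + 3 * (min_codon - 1), len(cds) - 1, 3):
        if cds[nt - 1 : nt + 2] != "ATG":
            continue
        context, strength, score = kozak_context(cds, nt)
        if strength.rank >= stringency.rank:
            sites.append(
                KozakSite(
                    nt_position=nt,
                    codon_index=(nt - 1) // 3 + 1,
                    strength=strength,
                    context=context,
                    in_frame=True,
                    consensus_score=score,
                )
            )
    return sites


@dataclass(frozen=True)
class TruncationReport:
    """Partition of a protein's annotated features under a truncation."""

    variant: ProteinConsequence
    retained_range: tuple[int, int]
    retained_features: tuple[tuple[str, int, int], ...]
    removed_features: tuple[tuple[str, int, int], ...]


def truncation_report(
    c: ProteinConsequence,
    features: Sequence[tuple[str, int, int]],
    protein_length: int,
) -> TruncationReport:
    """Report which features a truncating variant removes.

    Wild-type residues 1..k survive, where k is the retained wild-type
    length (a frameshift's novel tail carries no wild-type features). A
    feature is removed as soon as any part of it lies beyond residue k:
    partial loss counts as removed.
    """
    if c.consequence not in (Consequence.stop_gain, Consequence.frameshift):
        raise ValueError(f"not a truncating consequence: {c.consequence}")
    k = c.retained_wt_length or 0
    for name, start, end in features:
        if not (1 <= start <= end <= protein_length):
            raise ValueError(f"feature {name!r} interval ({start},{end}) outside protein")
    removed = tuple((n, s, e) for n, s, e in features if e > k)
    retained = tuple((n, s, e) for n, s, e in features if e <= k)
    return TruncationReport(
        variant=c,
        retained_range=(1, k),
        retained_features=retained,
        removed_features=removed,
    )


def predicted_mass(protein: str, fusion_partners: Sequence[str] = ()) -> float:
    """Predicted average molecular mass in kDa of a (fusion) protein.

    Average (not monoisotopic) residue masses, one water per chain, minus
    one water per fusion junction — the scale at which gel migration is
    compared.
    """
    chains = [protein, *fusion_partners]
    water = 18.0153
    total = 0.0
    for chain in chains:
        if not chain:
            raise ValueError("empty chain")
        total += molecular_weight(chain.upper(), seq_type="protein")
    total -= water * (len(chains) - 1)
    return total / 1000.0
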