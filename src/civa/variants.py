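"""Loss-of-function variant screening for chromosome segregation genes.

This module implements the prediction step of the CIVa (chromosomal
instability aiding variant) framework: parse protein-level HGVS variant
notation, classify loss-of-function consequences, collate heterozygous /
homozygous carrier counts across population databases, and apply the
prevalence filter that nominates truncating variants seen in at least two
individuals as CIVa candidates.

Carrier counts from different cohorts are never summed implicitly: cohorts
such as gnomAD and population-specific panels may overlap, so the filter
uses the maximum single-source carrier count by default and pooling is an
explicit opt-in (``sum_sources=True``).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Consequence",
    "LofClass",
    "ProteinConsequence",
    "VariantRecord",
    "CIVaCandidate",
    "HgvsParseError",
    "parse_hgvs_p",
    "format_hgvs_p",
    "classify_lof",
    "civa_filter",
    "merge_databases",
    "allele_frequency",
    "lollipop_export",
    "civa_db_export",
    "civa_db_import",
    "read_variant_table",
    "candidates_table",
]


class Consequence(str, Enum):
    """Protein-level consequence class of a variant."""

    stop_gain = "stop_gain"
    frameshift = "frameshift"
    start_loss = "start_loss"
    missense = "missense"
    synonymous = "synonymous"
    other = "other"


class LofClass(str, Enum):
    """Loss-of-function category used by the CIVa screen."""

    truncating = "truncating"
    start_loss = "start_loss"
    non_lof = "non_lof"


class HgvsParseError(ValueError):
    """Raised when a protein HGVS string cannot be interpreted."""

    def __init__(self, notation: str, token: str, reason: str):
        self.notation = notation
        self.token = token
        super().__init__(f"cannot parse {notation!r}: {reason} (offending token: {token!r})")


# Three-letter to one-letter amino-acid code, plus the HGVS stop spellings.
_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

_RE_WRAP = re.compile(r"^\s*(?:p\.)?\(?\s*(.+?)\s*\)?\s*$")
# one- or three-letter residue token
_AA_TOK = r"(\*|Ter|X|[A-Z][a-z]{2}|[A-Z])"
_RE_BODY = re.compile(
    rf"^{_AA_TOK}(\d+)(?:"
    rf"(?P<fs>{_AA_TOK}?fs(?:\*|Ter)(?P<fslen>\d+))"
    rf"|(?P<stop>\*|Ter|X)"
    rf"|(?P<syn>=)"
    rf"|(?P<startloss>\?)"
    rf"|(?P<sub>{_AA_TOK})"
    rf")?$"
)


def _aa1(token: str, notation: str) -> str:
    """Normalize an amino-acid token to its one-letter code."""
    if token in ("*", "X", "Ter"):
        return "*"
    if len(token) == 1:
        if token not in _AA1:
            raise HgvsParseError(notation, token, "unknown amino-acid code")
        return token
    try:
        return _AA3_TO_1[token]
    except KeyError:
        raise HgvsParseError(notation, token, "unknown amino-acid code") from None


@dataclass(frozen=True)
class ProteinConsequence:
    """Derived consequence of a protein HGVS variant.

    ``retained_wt_length`` counts wild-type residues preserved before the
    first affected position; ``novel_tail_length`` counts non-wild-type
    residues appended by a frameshift before its new stop.
    ``truncated_total_length`` (retained + novel tail) is the predicted
    length of the truncated product and is ``None`` for non-truncating
    classes.
    """

    consequence: Consequence
    ref_aa: str
    first_affected_residue: int
    alt_aa: str | None = None
    retained_wt_length: int | None = None
    novel_tail_length: int | None = None
    truncated_total_length: int | None = None

    @property
    def is_truncating(self) -> bool:
        return self.consequence in (Consequence.stop_gain, Consequence.frameshift)


def parse_hgvs_p(notation: str) -> ProteinConsequence:
    """Parse a protein-level HGVS string into a :class:`ProteinConsequence`.

    Supports the dialect used by population-database exports: optional
    ``p.`` prefix and parentheses, one- and three-letter codes, and the
    classes stop-gain (``Q1012*``), frameshift (``L7Qfs*21``), start loss
    (``M1?``), missense (``V5M``) and synonymous (``K10=``). Anything else
    (in-frame indels, extensions, splice notation) is classed ``other``
    with a warning rather than rejected.

    >>> parse_hgvs_p("p.(L7Qfs*21)").truncated_total_length
    26
    """
    if not notation or not notation.strip():
        raise HgvsParseError(notation, "", "empty notation")
    body = _RE_WRAP.match(notation).group(1)
    m = _RE_BODY.match(body)
    if m is None:
        # unsupported but syntactically HGVS-ish notation -> class "other"
        if re.match(rf"^{_AA_TOK}\d+", body):
            warnings.warn(
                f"unsupported HGVS.p form {notation!r}; classed as 'other'",
                stacklevel=2,
            )
            head = re.match(rf"^{_AA_TOK}(\d+)", body)
            pos = int(head.group(2))
            if pos == 0:
                raise HgvsParseError(notation, head.group(2), "residue position 0")
            return ProteinConsequence(Consequence.other, _aa1(head.group(1), notation), pos)
        raise HgvsParseError(notation, body, "not a recognised protein variant")

    ref = _aa1(m.group(1), notation)
    pos = int(m.group(2))
    if pos == 0:
        raise HgvsParseError(notation, m.group(2), "residue position 0")

    if m.group("fs") is not None:
        n = int(m.group("fslen"))
        if n < 1:
            raise HgvsParseError(notation, m.group("fslen"), "fs*N requires N >= 1")
        alt_tok = m.group(4)  # first residue of the shifted frame, optional
        alt = _aa1(alt_tok, notation) if alt_tok else None
        retained = pos - 1
        tail = n - 1
        return ProteinConsequence(
            Consequence.frameshift, ref, pos, alt,
            retained_wt_length=retained,
            novel_tail_length=tail,
            truncated_total_length=retained + tail,
        )
    if m.group("stop") is not None:
        return ProteinConsequence(
            Consequence.stop_gain, ref, pos, "*",
            retained_wt_length=pos - 1,
            novel_tail_length=0,
            truncated_total_length=pos - 1,
        )
    if m.group("startloss") is not None:
        if ref != "M" or pos != 1:
            raise HgvsParseError(notation, body, "'?' consequence only valid for Met1")
        return ProteinConsequence(Consequence.start_loss, "M", 1, None)
    if m.group("syn") is not None:
        return ProteinConsequence(Consequence.synonymous, ref, pos, ref)
    if m.group("sub") is not None:
        alt = _aa1(m.group("sub"), notation)
        if alt == "*":
            # X1012* style already handled above; defensive
            return ProteinConsequence(
                Consequence.stop_gain, ref, pos, "*",
                retained_wt_length=pos - 1, novel_tail_length=0,
                truncated_total_length=pos - 1,
            )
        cls = Consequence.synonymous if alt == ref else Consequence.missense
        if ref == "M" and pos == 1 and cls is Consequence.missense:
            cls = Consequence.start_loss
        return ProteinConsequence(cls, ref, pos, alt)
    # bare "Q1012" with no consequence suffix
    raise HgvsParseError(notation, body, "missing consequence suffix")


def format_hgvs_p(c: ProteinConsequence) -> str:
    """Canonical one-letter rendering of a parsed consequence."""
    if c.consequence is Consequence.stop_gain:
        return f"{c.ref_aa}{c.first_affected_residue}*"
    if c.consequence is Consequence.frameshift:
        alt = c.alt_aa or ""
        return f"{c.ref_aa}{c.first_affected_residue}{alt}fs*{(c.novel_tail_length or 0) + 1}"
    if c.consequence is Consequence.start_loss:
        return "M1?"
    if c.consequence is Consequence.synonymous:
        return f"{c.ref_aa}{c.first_affected_residue}="
    if c.consequence is Consequence.missense:
        return f"{c.ref_aa}{c.first_affected_residue}{c.alt_aa}"
    return f"{c.ref_aa}{c.first_affected_residue}?other"


def classify_lof(c: ProteinConsequence) -> LofClass:
    """Map a consequence to the loss-of-function category of the screen."""
    if c.consequence in (Consequence.stop_gain, Consequence.frameshift):
        return LofClass.truncating
    if c.consequence is Consequence.start_loss:
        return LofClass.start_loss
    return LofClass.non_lof


@dataclass
class VariantRecord:
    """One gene variant with per-source heterozygous/homozygous counts."""

    gene_symbol: str
    hgvs_p: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    uniprot_id: str | None = None
    protein_length: int | None = None
    consequence: Consequence | None = None

    def __post_init__(self) -> None:
        self._parsed = parse_hgvs_p(self.hgvs_p)
        if self.consequence is None:
            self.consequence = self._parsed.consequence
        elif self.consequence != self._parsed.consequence:
            raise ValueError(
                f"{self.gene_symbol} {self.hgvs_p}: stated consequence "
                f"{self.consequence} contradicts parsed {self._parsed.consequence}"
            )
        for src, (het, hom) in self.counts.items():
            if het < 0 or hom < 0:
                raise ValueError(f"negative count for source {src!r}")

    @property
    def parsed(self) -> ProteinConsequence:
        return self._parsed

    @property
    def residue_position(self) -> int:
        return self._parsed.first_affected_residue

    def carriers(self, sum_sources: bool = False) -> int:
        """Carrier individuals: max single source by default, pooled on request."""
        per_source = [het + hom for het, hom in self.counts.values()]
        if not per_source:
            return 0
        return sum(per_source) if sum_sources else max(per_source)

    def total_hom(self) -> int:
        return sum(hom for _, hom in self.counts.values())


@dataclass
class CIVaCandidate:
    """A truncating variant passing the prevalence filter."""

    variant: VariantRecord
    n_individuals: int
    homozygous_observed: bool
    allele_frequency: float | None = None


def _canonical_key(rec: VariantRecord) -> tuple[str, str]:
    return rec.gene_symbol, format_hgvs_p(rec.parsed)


def civa_filter(
    records: Iterable[VariantRecord],
    min_individuals: int = 2,
    sum_sources: bool = False,
) -> list[CIVaCandidate]:
    """Nominate CIVa candidates: truncating variants carried by at least
    ``min_individuals`` people.

    The individual count is ``het + hom`` carriers; by default the maximum
    over sources (conservative under cohort overlap), pooled across sources
    when ``sum_sources`` is set. Output is sorted by (gene, residue
    position, class) for reproducibility.
    """
    if min_individuals < 1:
        raise ValueError("min_individuals must be >= 1")
    out: list[CIVaCandidate] = []
    for rec in records:
        if classify_lof(rec.parsed) is not LofClass.truncating:
            continue
        n = rec.carriers(sum_sources=sum_sources)
        if n >= min_individuals:
            out.append(
                CIVaCandidate(
                    variant=rec,
                    n_individuals=n,
                    homozygous_observed=rec.total_hom() >= 1,
                )
            )
    out.sort(key=lambda c: (c.variant.gene_symbol,
                            c.variant.residue_position,
                            c.variant.consequence.value))
    return out


def merge_databases(
    tables: Sequence[tuple[str, Sequence[VariantRecord]]],
) -> list[VariantRecord]:
    """Unify per-database variant tables into one record per variant.

    Records are keyed by (gene symbol, canonical HGVS.p); the merged record
    keeps one (het, hom) entry per source and never sums counts across
    sources. Each input record must carry exactly one source entry, and the
    same variant must not be classed differently by two databases.
    """
    merged: dict[tuple[str, str], VariantRecord] = {}
    for source_name, records in tables:
        for rec in records:
            if len(rec.counts) != 1:
                raise ValueError(
                    f"{rec.gene_symbol} {rec.hgvs_p}: expected exactly one "
                    f"source entry, got {sorted(rec.counts)}"
                )
            ((src, counts),) = rec.counts.items()
            if src != source_name:
                raise ValueError(
                    f"{rec.gene_symbol} {rec.hgvs_p}: record source {src!r} "
                    f"does not match table {source_name!r}"
                )
            key = _canonical_key(rec)
            if key not in merged:
                merged[key] = VariantRecord(
                    gene_symbol=rec.gene_symbol,
                    hgvs_p=format_hgvs_p(rec.parsed),
                    counts={src: counts},
                    uniprot_id=rec.uniprot_id,
                    protein_length=rec.protein_length,
                )
            else:
                tgt = merged[key]
                if tgt.consequence != rec.consequence:
                    raise ValueError(
                        f"conflicting consequence classes for {key}: "
                        f"{tgt.consequence} vs {rec.consequence}"
                    )
                if src in tgt.counts:
                    raise ValueError(f"duplicate source {src!r} for {key}")
                tgt.counts[src] = counts
                if tgt.uniprot_id is None:
                    tgt.uniprot_id = rec.uniprot_id
                if tgt.protein_length is None:
                    tgt.protein_length = rec.protein_length
    out = list(merged.values())
    out.sort(key=lambda r: (r.gene_symbol, r.residue_position,
                            r.consequence.value, r.hgvs_p))
    return out


def allele_frequency(het: int, hom: int, n_individuals: int) -> float:
    """Diploid allele frequency (het + 2·hom) / (2·n_individuals)."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if het < 0 or hom < 0:
        raise ValueError("counts must be non-negative")
    if het + hom > n_individuals:
        raise ValueError("het + hom carriers exceed n_individuals")
    return (het + 2 * hom) / (2 * n_individuals)


_LOLLIPOP_CATEGORY = {
    Consequence.stop_gain: "truncating",
    Consequence.frameshift: "truncating",
    Consequence.missense: "missense",
    Consequence.start_loss: "other",
    Consequence.synonymous: "other",
    Consequence.other: "other",
}


def lollipop_export(gene: str, records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Tabulate a gene's variants for a lollipop plot.

    One row per (residue position, category) with the number of carrier
    occurrences (pooled across sources, as on a published lollipop track)
    and the number of homozygous occurrences. Categories are truncating /
    missense / other.
    """
    rows: dict[tuple[int, str], list[int]] = {}
    for rec in records:
        if rec.gene_symbol != gene:
            raise ValueError(
                f"record for {rec.gene_symbol!r} passed to lollipop export of {gene!r}"
            )
        cat = _LOLLIPOP_CATEGORY[rec.consequence]
        key = (rec.residue_position, cat)
        occ = sum(het + hom for het, hom in rec.counts.values())
        hom = rec.total_hom()
        if key in rows:
            rows[key][0] += occ
            rows[key][1] += hom
        else:
            rows[key] = [occ, hom]
    table = pd.DataFrame(
        [(pos, cat, occ, hom) for (pos, cat), (occ, hom) in sorted(rows.items())],
        columns=["position", "category", "count", "hom_count"],
    )
    return table


def civa_db_export(
    genes: Sequence[tuple[str, str | None, Sequence[VariantRecord]]],
) -> dict:
    """Build the queryable CIVa database document.

    The JSON document is keyed for lookup by gene symbol (``genes``) and by
    UniProt ID (``by_uniprot``, mapping to the symbol). Round-trips through
    :func:`civa_db_import`.
    """
    doc: dict = {"genes": {}, "by_uniprot": {}}
    for symbol, uniprot, records in genes:
        if symbol in doc["genes"]:
            raise ValueError(f"duplicate gene symbol {symbol!r}")
        variants = []
        for rec in sorted(records, key=lambda r: (r.residue_position, r.hgvs_p)):
            variants.append(
                {
                    "hgvs_p": format_hgvs_p(rec.parsed),
                    "class": rec.consequence.value,
                    "sources": {
                        src: {"het": het, "hom": hom}
                        for src, (het, hom) in sorted(rec.counts.items())
                    },
                }
            )
        doc["genes"][symbol] = {
            "symbol": symbol,
            "uniprot": uniprot,
            "variants": variants,
        }
        if uniprot:
            doc["by_uniprot"][uniprot] = symbol
    return doc


def civa_db_import(doc: dict) -> list[tuple[str, str | None, list[VariantRecord]]]:
    """Inverse of :func:`civa_db_export`."""
    out = []
    for symbol, entry in doc["genes"].items():
        records = [
            VariantRecord(
                gene_symbol=symbol,
                hgvs_p=v["hgvs_p"],
                counts={s: (c["het"], c["hom"]) for s, c in v["sources"].items()},
                uniprot_id=entry.get("uniprot"),
            )
            for v in entry["variants"]
        ]
        out.append((symbol, entry.get("uniprot"), records))
    return out


def read_variant_table(path: str) -> list[VariantRecord]:
    """Read a variant table (TSV/CSV with header gene,hgvs_p,source,het,hom)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"gene", "hgvs_p", "source", "het", "hom"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            VariantRecord(
                gene_symbol=str(row["gene"]),
                hgvs_p=str(row["hgvs_p"]),
                counts={str(row["source"]): (int(row["het"]), int(row["hom"]))},
                uniprot_id=str(row["uniprot"]) if "uniprot" in df.columns and pd.notna(row.get("uniprot")) else None,
            )
        )
    return records


def read_variant_vcf(
    path: str,
    hgvsp_key: str = "HGVSP",
    gene_key: str = "GENE",
    source_key: str = "SRC",
) -> list[VariantRecord]:
    """Read a minimal VCF whose INFO field carries protein annotations.

    Only records with the named HGVS.p INFO key are ingested; consequence
    calling from genomic coordinates is deliberately not attempted. Carrier
    counts are taken from INFO keys ``HET`` and ``HOM`` (default 0).
    """
    import pysam

    records = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = rec.info
            if hgvsp_key not in info:
                continue
            hgvsp = info[hgvsp_key]
            if isinstance(hgvsp, tuple):
                hgvsp = hgvsp[0]
            gene = info.get(gene_key, rec.chrom)
            if isinstance(gene, tuple):
                gene = gene[0]
            source = info.get(source_key, "VCF")
            if isinstance(source, tuple):
                source = source[0]
            het = int(info.get("HET", 0))
            hom = int(info.get("HOM", 0))
            records.append(
                VariantRecord(
                    gene_symbol=str(gene),
                    hgvs_p=str(hgvsp),
                    counts={str(source): (het, hom)},
                )
            )
    return records


def candidates_table(candidates: Sequence[CIVaCandidate]) -> pd.DataFrame:
    """Flatten filter output for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene": c.variant.gene_symbol,
                "hgvs_p": format_hgvs_p(c.variant.parsed),
                "class": c.variant.consequence.value,
                "n_individuals": c.n_individuals,
                "homozygous_observed": c.homozygous_observed,
                "allele_frequency": c.allele_frequency,
            }
            for c in candidates
        ],
        columns=["gene", "hgvs_p", "class", "n_individuals",
                 "homozygous_observed", "allele_frequency"],
    )


def write_civa_db(doc: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
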