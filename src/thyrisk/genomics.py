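"""Genomic alterations, annotation weights and the genomic classifier score.

The genomic classifier score X_GC of a nodule is an additive evidence score:
every somatic alteration detected in the nodule is annotated with a weight in
[0, 1] expressing its strength of association with thyroid cancer (0 = no
association, 1 = pathognomonic), and the score is the sum

    X_GC = sum over SNV/INDEL weights + sum over fusion weights + sum over CNV weights.

The sum is intentionally uncapped: a nodule carrying several alterations can
exceed 1, and the downstream cutoff analysis operates on the raw sum.

Weights are supplied through a :class:`WeightTable` (TSV or JSON on disk, or
the bundled :func:`default_weight_table`). Alterations absent from the table
map to the table's ``fallback_weight`` (default 0) with a logged warning,
because pan-cancer panels routinely report variants with no thyroid-specific
annotation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


class AlterationClass(str, Enum):
    """The four alteration classes reported by targeted pan-cancer panels."""

    SNV = "SNV"
    INDEL = "INDEL"
    GENE_FUSION = "GENE_FUSION"
    CNV = "CNV"


def infer_alteration_class(detail: str) -> AlterationClass:
    """Heuristically classify an alteration from its ``detail`` string.

    Rules (first match wins):

    * contains ``amplification``/``deletion``/``gain``/``loss`` -> CNV
    * HGVS-style ``p.``/``c.`` containing ``del``/``ins``/``dup``/``fs`` -> INDEL
    * other ``p.``/``c.`` -> SNV
    * ``A-B`` gene-pair form (e.g. ``PAX8-PPARG``) -> GENE_FUSION
    * anything else -> SNV

    Used when reading cohort CSVs, where alterations are stored as bare
    ``GENE:detail`` identifiers; the variants TSV format carries an explicit
    class column and does not rely on inference.
    """
    d = detail.strip()
    low = d.lower()
    if any(k in low for k in ("amplification", "deletion", "gain", "loss")):
        return AlterationClass.CNV
    if low.startswith(("p.", "c.")):
        if any(k in low for k in ("del", "ins", "dup", "fs")):
            return AlterationClass.INDEL
        return AlterationClass.SNV
    if "-" in d and d.replace("-", "").isalnum() and d.upper() == d:
        return AlterationClass.GENE_FUSION
    return AlterationClass.SNV


@dataclass(frozen=True)
class GenomicAlteration:
    """A single somatic alteration of a nodule.

    ``identifier`` is the canonical lookup key ``GENE:detail`` with the gene
    symbol uppercased and the detail whitespace-trimmed but otherwise verbatim,
    so that the same variant written in different files maps to the same weight.
    """

    gene: str
    alteration_class: AlterationClass
    detail: str

    def __post_init__(self):
        if not self.gene.strip():
            raise ValidationError("empty-gene", "alteration gene symbol is empty")
        if not self.detail.strip():
            raise ValidationError("empty-detail", "alteration detail is empty")
        if not isinstance(self.alteration_class, AlterationClass):
            raise ValidationError(
                "bad-class", f"invalid alteration class {self.alteration_class!r}"
            )

    @property
    def identifier(self) -> str:
        return f"{self.gene.strip().upper()}:{self.detail.strip()}"

    @classmethod
    def from_identifier(cls, identifier: str) -> "GenomicAlteration":
        """Build an alteration from a ``GENE:detail`` string, inferring class."""
        gene, sep, detail = identifier.partition(":")
        if not sep or not gene.strip() or not detail.strip():
            raise ParseError(
                "bad-identifier", f"cannot parse alteration identifier {identifier!r}"
            )
        return cls(gene=gene, alteration_class=infer_alteration_class(detail), detail=detail)


def _check_weight(identifier: str, weight: float) -> float:
    try:
        w = float(weight)
    except (TypeError, ValueError):
        raise ParseError("non-numeric-weight", f"weight for {identifier!r} is not numeric")
    if math.isnan(w) or not (0.0 <= w <= 1.0):
        raise ValidationError(
            "weight-out-of-range", f"weight {weight!r} for {identifier!r} outside [0, 1]"
        )
    return w


@dataclass
class WeightTable:
    """Map from alteration identifier to annotation weight in [0, 1].

    ``fallback_weight`` is returned for identifiers absent from the table;
    ``provenance`` optionally records a free-text note per entry (database,
    prevalence ratio, curation comment).
    """

    entries: dict[str, float]
    fallback_weight: float = 0.0
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.entries = {k: _check_weight(k, v) for k, v in self.entries.items()}
        self.fallback_weight = _check_weight("_fallback", self.fallback_weight)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.entries


def load_weight_table(path: str | Path, format: str | None = None) -> WeightTable:
    """Load a :class:`WeightTable` from TSV or JSON.

    TSV: header ``identifier<TAB>weight<TAB>provenance`` (provenance optional),
    UTF-8, lines starting with ``#`` skipped. JSON: flat object mapping
    identifier to weight, with an optional ``"_fallback"`` key.

    ``format`` is ``"tsv"`` or ``"json"``; inferred from the suffix if omitted.
    Duplicate identifiers and weights outside [0, 1] are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError("missing-file", f"weight table not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(data, Mapping):
            raise ParseError("malformed-json", "weight JSON must be a flat object")
        fallback = data.pop("_fallback", 0.0) if "_fallback" in data else 0.0
        return WeightTable(entries=dict(data), fallback_weight=fallback)
    if fmt != "tsv":
        raise ParseError("unknown-format", f"unknown weight table format {fmt!r}")

    entries: dict[str, float] = {}
    provenance: dict[str, str] = {}
    fallback = 0.0
    header_seen = False
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if not header_seen:
            if [c.strip().lower() for c in cells[:2]] != ["identifier", "weight"]:
                raise ParseError(
                    "missing-header", "expected header 'identifier\\tweight[\\tprovenance]'",
                    row=lineno,
                )
            header_seen = True
            continue
        if len(cells) < 2:
            raise ParseError("malformed-row", f"expected >= 2 columns, got {len(cells)}", row=lineno)
        ident = cells[0].strip()
        if ident == "_fallback":
            fallback = _check_weight(ident, cells[1])
            continue
        if ident in entries:
            raise ParseError("duplicate-identifier", f"duplicate identifier {ident!r}", row=lineno)
        entries[ident] = _check_weight(ident, cells[1])
        if len(cells) >= 3 and cells[2].strip():
            provenance[ident] = cells[2].strip()
    if not header_seen:
        raise ParseError("missing-header", "weight table has no header row")
    return WeightTable(entries=entries, fallback_weight=fallback, provenance=provenance)


def annotate_alteration(alteration: GenomicAlteration, table: WeightTable) -> float:
    """Return the annotation weight for one alteration.

    Unknown identifiers map to ``table.fallback_weight`` and emit a warning on
    the module logger — never an error, since pan-cancer panels report variants
    absent from any thyroid-focused table.
    """
    ident = alteration.identifier
    if ident in table.entries:
        return table.entries[ident]
    logger.warning(
        "unknown alteration %s: using fallback weight %g", ident, table.fallback_weight
    )
    return table.fallback_weight


@dataclass(frozen=True)
class GenomicProfile:
    """A nodule's alterations together with its genomic classifier score.

    ``components`` is the triple (SNV/INDEL sum, fusion sum, CNV sum) whose
    total is ``x_gc``; an empty alteration list scores exactly 0.
    """

    nodule_id: str
    alterations: tuple[GenomicAlteration, ...]
    x_snv_indel_sum: float
    x_gf: float
    x_cnv: float

    @property
    def x_gc(self) -> float:
        return self.x_snv_indel_sum + self.x_gf + self.x_cnv

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.x_snv_indel_sum, self.x_gf, self.x_cnv)


def compute_xgc(
    alterations: Iterable[GenomicAlteration],
    table: WeightTable,
    nodule_id: str = "",
) -> GenomicProfile:
    """Compute the genomic classifier score of a nodule.

    The three components sum per-variant weights by class: all SNVs and INDELs
    contribute to the first component (one term per variant), fusions to the
    second, CNVs to the third. The result is order-independent and additive
    over disjoint alteration lists.
    """
    alts = tuple(alterations)
    snv_indel = gf = cnv = 0.0
    for a in alts:
        w = annotate_alteration(a, table)
        if a.alteration_class in (AlterationClass.SNV, AlterationClass.INDEL):
            snv_indel += w
        elif a.alteration_class is AlterationClass.GENE_FUSION:
            gf += w
        else:
            cnv += w
    return GenomicProfile(
        nodule_id=nodule_id,
        alterations=alts,
        x_snv_indel_sum=snv_indel,
        x_gf=gf,
        x_cnv=cnv,
    )


#: Illustrative default annotation weights. The values encode the qualitative
#: ordering used throughout thyroid molecular diagnostics — BRAF V600E and RET
#: hotspots near-certain drivers, RAS hotspots intermediate (seen in both
#: benign and malignant follicular lesions), passenger-like variants low — but
#: they are package defaults, not published study values (no per-alteration
#: weight table has been published); analyses should pass weights explicitly.
DEFAULT_WEIGHTS: dict[str, float] = {
    "BRAF:p.Val600Glu": 0.95,
    "TERT:c.1-124C>T": 0.80,
    "RET:p.Cys634Arg": 0.95,
    "RET:p.Met918Thr": 0.95,
    "RET:deletion": 0.90,
    "PAX8:PAX8-PPARG": 0.90,
    "NRAS:p.Gln61Arg": 0.65,
    "KRAS:p.Gln61Arg": 0.65,
    "HRAS:p.Gln61Arg": 0.55,
    "NRAS:p.Gln61Lys": 0.50,
    "SLX4:p.Glu1517Ter": 0.20,
    "ATM:p.Asp2708Asn": 0.15,
    "GNAS:p.Arg201Cys": 0.15,
    "ESR1:p.Tyr537Ser": 0.10,
    "TET2:p.Gln742Ter": 0.10,
    "CCND1:amplification": 0.25,
}


def default_weight_table() -> WeightTable:
    """The bundled default weight table (see :data:`DEFAULT_WEIGHTS`)."""
    return WeightTable(
        entries=dict(DEFAULT_WEIGHTS),
        fallback_weight=0.0,
        provenance={k: "thyrisk default (illustrative)" for k in DEFAULT_WEIGHTS},
    )
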