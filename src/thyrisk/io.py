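"""File formats: cohort CSV, per-nodule variants TSV, scored CSV, reports.

All formats are plain text (UTF-8), versioned with a ``# format_version``
header comment, and written canonically so that identical inputs produce
byte-identical files. Cohort alterations are stored as semicolon-joined
``GENE:detail`` identifiers; alteration classes are re-inferred on read (the
variants TSV keeps an explicit class column when inference is not wanted).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .cohort import Histology, SyntheticNodule, truth_of
from .errors import ParseError
from .genomics import AlterationClass, GenomicAlteration
from .risk import Management, ScoredNodule, Truth
from .ultrasound import AtaPattern, parse_pattern, xus_from_pattern

FORMAT_VERSION = 1
_HEADER_COMMENT = f"# format_version: {FORMAT_VERSION}\n"

COHORT_COLUMNS = ["nodule_id", "histology", "truth", "us_pattern", "alterations"]
SCORED_COLUMNS = ["nodule_id", "x_us", "x_gc", "trs", "recommendation", "truth"]


def _fmt_score(x: float) -> str:
    """Canonical decimal rendering of a score (scores live on a 0.05 lattice)."""
    return format(round(x, 10), "g")


def write_cohort(nodules: Sequence[SyntheticNodule], path: str | Path) -> None:
    lines = [_HEADER_COMMENT, ",".join(COHORT_COLUMNS) + "\n"]
    for n in nodules:
        alts = ";".join(a.identifier for a in n.alterations)
        lines.append(
            f"{n.nodule_id},{n.histology.value},{n.truth.value},{n.pattern.value},{alts}\n"
        )
    Path(path).write_text("".join(lines), encoding="utf-8")


def _data_rows(path: Path, sep: str) -> Iterable[tuple[int, list[str]]]:
    if not path.exists():
        raise ParseError("missing-file", f"file not found: {path}")
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split(sep)


def read_cohort(path: str | Path) -> list[SyntheticNodule]:
    """Read a cohort CSV.

    Requires ``nodule_id``; accepts ``us_pattern`` (names) and/or ``x_us``
    (numeric) — when both are present they must agree. ``histology`` and
    ``truth`` are optional (truth defaults from histology when present).
    """
    path = Path(path)
    header: Optional[dict[str, int]] = None
    nodules: list[SyntheticNodule] = []
    for lineno, cells in _data_rows(path, ","):
        if header is None:
            header = {name.strip(): i for i, name in enumerate(cells)}
            if "nodule_id" not in header:
                raise ParseError("missing-column", "cohort CSV needs a nodule_id column", row=lineno)
            if "us_pattern" not in header and "x_us" not in header:
                raise ParseError(
                    "missing-column", "cohort CSV needs us_pattern or x_us", row=lineno
                )
            continue

        def cell(name: str) -> str:
            i = header.get(name)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        nodule_id = cell("nodule_id")
        if not nodule_id:
            raise ParseError("missing-id", "empty nodule_id", row=lineno)
        pattern: Optional[AtaPattern] = None
        if cell("us_pattern"):
            pattern = parse_pattern(cell("us_pattern"))
        if cell("x_us"):
            numeric = parse_pattern(cell("x_us"))
            if pattern is not None and abs(
                xus_from_pattern(pattern) - xus_from_pattern(numeric)
            ) > 1e-9:
                raise ParseError(
                    "pattern-mismatch",
                    f"us_pattern {cell('us_pattern')!r} disagrees with x_us {cell('x_us')!r}",
                    row=lineno,
                )
            pattern = pattern or numeric
        alterations = tuple(
            GenomicAlteration.from_identifier(ident.strip())
            for ident in cell("alterations").split(";")
            if ident.strip()
        )
        hist_text = cell("histology")
        try:
            histology = Histology(hist_text) if hist_text else None
        except ValueError:
            raise ParseError("bad-histology", f"unknown histology {hist_text!r}", row=lineno)
        truth_text = cell("truth")
        if truth_text:
            try:
                truth = Truth(truth_text.upper())
            except ValueError:
                raise ParseError("bad-truth", f"unknown truth label {truth_text!r}", row=lineno)
        elif histology is not None:
            truth = truth_of(histology)
        else:
            truth = None
        if histology is not None and truth is not None and truth_of(histology) is not truth:
            raise ParseError(
                "truth-mismatch", f"truth {truth.value} inconsistent with histology", row=lineno
            )
        nodules.append(
            SyntheticNodule(
                nodule_id=nodule_id,
                histology=histology,
                truth=truth,
                pattern=pattern,
                alterations=alterations,
            )
        )
    if header is None:
        raise ParseError("empty-input", f"cohort file {path} is empty")
    if not nodules:
        raise ParseError("empty-input", f"cohort file {path} has no data rows")
    return nodules


def read_variants_tsv(path: str | Path) -> dict[str, list[GenomicAlteration]]:
    """Read a per-nodule variant list TSV: ``nodule_id, gene, class, detail``."""
    path = Path(path)
    header: Optional[dict[str, int]] = None
    out: dict[str, list[GenomicAlteration]] = {}
    for lineno, cells in _data_rows(path, "\t"):
        if header is None:
            header = {name.strip(): i for i, name in enumerate(cells)}
            missing = {"nodule_id", "gene", "class", "detail"} - set(header)
            if missing:
                raise ParseError("missing-column", f"variants TSV lacks {sorted(missing)}", row=lineno)
            continue
        if len(cells) < len(header):
            raise ParseError("malformed-row", f"expected {len(header)} columns", row=lineno)
        try:
            cls = AlterationClass(cells[header["class"]].strip().upper())
        except ValueError:
            raise ParseError(
                "bad-class", f"unknown alteration class {cells[header['class']]!r}", row=lineno
            )
        alt = GenomicAlteration(
            gene=cells[header["gene"]], alteration_class=cls, detail=cells[header["detail"]]
        )
        out.setdefault(cells[header["nodule_id"]].strip(), []).append(alt)
    if header is None:
        raise ParseError("empty-input", f"variants file {path} is empty")
    return out


def write_scored(scored: Sequence[ScoredNodule], path: str | Path) -> None:
    lines = [_HEADER_COMMENT, ",".join(SCORED_COLUMNS) + "\n"]
    for s in scored:
        truth = s.truth.value if s.truth is not None else ""
        lines.append(
            f"{s.nodule_id},{_fmt_score(s.x_us)},{_fmt_score(s.x_gc)},"
            f"{_fmt_score(s.trs)},{s.recommendation.value},{truth}\n"
        )
    Path(path).write_text("".join(lines), encoding="utf-8")


def read_scored(path: str | Path) -> list[ScoredNodule]:
    path = Path(path)
    header: Optional[dict[str, int]] = None
    out: list[ScoredNodule] = []
    for lineno, cells in _data_rows(path, ","):
        if header is None:
            header = {name.strip(): i for i, name in enumerate(cells)}
            missing = set(SCORED_COLUMNS[:-1]) - set(header)
            if missing:
                raise ParseError("missing-column", f"scored CSV lacks {sorted(missing)}", row=lineno)
            continue

        def cell(name: str) -> str:
            i = header.get(name)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        truth = Truth(cell("truth").upper()) if cell("truth") else None
        try:
            out.append(
                ScoredNodule(
                    nodule_id=cell("nodule_id"),
                    x_us=float(cell("x_us")),
                    x_gc=float(cell("x_gc")),
                    trs=float(cell("trs")),
                    recommendation=Management(cell("recommendation")),
                    truth=truth,
                )
            )
        except ValueError as exc:
            raise ParseError("malformed-row", str(exc), row=lineno)
    if header is None or not out:
        raise ParseError("empty-input", f"scored file {path} has no data rows")
    return out


def write_report_json(report: dict, path: str | Path) -> None:
    payload = {"format_version": FORMAT_VERSION, **report}
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8"
    )
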