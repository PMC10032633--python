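"""Report generation, literature search strings, single/batch entry points
and run logging.

TSV is the canonical, byte-stable report format; the spreadsheet (.xlsx)
export is a presentation layer carrying identical cell content. Batch runs
process rows sequentially and in isolation (one row's failure never aborts
the batch), writing a fresh timestamped log with exactly one entry per
input row.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from .codon_context import load_assay_table
from .combiner import combine, load_exclusion_rules
from .evidence_io import (
    BundleSchemaError,
    config_for_gene,
    load_evidence_bundle,
    load_gene_config,
)
from .hgvs import (
    HgvsParseError,
    parse_cdna_description,
    validate_supported_variant,
)
from .models import ClassificationResult, CriterionCall, State, Strength, VariantDescriptor

PathLike = Union[str, Path]

_AA_3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}
_AA_1 = {v: k for k, v in _AA_3.items()}


def _aa_forms(aa: str) -> tuple[str, str]:
    """(one-letter, three-letter) forms of an amino-acid token."""
    if aa in _AA_3:
        return aa, _AA_3[aa]
    if aa in _AA_1:
        return _AA_1[aa], aa
    return aa, aa


def build_search_string(
    d: VariantDescriptor,
    protein_change: Optional[tuple[str, int, str]] = None,
) -> str:
    """OR-joined quoted aliases of a variant for internet search engines.

    Aliases cover the coding-DNA name with and without the ``c.`` prefix
    and with a space after it, plus (when a protein change is known) the
    one-letter and three-letter protein forms; the gene symbol is
    conjoined so searches stay on target.
    """
    aliases: list[str] = []
    cdna = d.cdna
    aliases.append(cdna)
    aliases.append(cdna[2:] if cdna.startswith("c.") else cdna)
    if cdna.startswith("c."):
        aliases.append("c. " + cdna[2:])
    if protein_change is not None:
        ref1, ref3 = _aa_forms(protein_change[0])
        alt1, alt3 = _aa_forms(protein_change[2])
        idx = protein_change[1]
        aliases.append(f"{ref1}{idx}{alt1}")
        aliases.append(f"{ref3}{idx}{alt3}")
        aliases.append(f"p.({ref3}{idx}{alt3})")
    seen: list[str] = []
    for a in aliases:
        if a not in seen:
            seen.append(a)
    joined = " OR ".join(f'"{a}"' for a in seen)
    return f"{d.gene_symbol} AND ({joined})"


# --------------------------------------------------------------------------
# report writer
# --------------------------------------------------------------------------

_COLUMNS = ["code", "state", "strength", "points", "source", "explanation", "warnings"]


def _report_rows(result: ClassificationResult,
                 search_string: str = "") -> list[list[str]]:
    """The canonical cell grid shared by the TSV and xlsx writers."""
    rows: list[list[str]] = []
    rows.append(["# variant", result.variant_key])
    rows.append(list(_COLUMNS))
    for call in result.calls:
        rows.append([
            call.code, call.state.value, call.strength.value, str(call.points),
            call.source, call.explanation, " | ".join(call.warnings),
        ])
    rows.append(["## active", ",".join(c.code for c in result.active)])
    rows.append(["## total_points", str(result.total_points)])
    rows.append(["## classification", result.classification.value])
    rows.append(["## ba1_standalone", str(result.ba1_standalone).lower()])
    rows.append(["## dropped", " | ".join(
        f"{code}->{kept}: {why}" for code, kept, why in result.dropped)])
    rows.append(["## warnings", " | ".join(result.warnings)])
    rows.append(["## search_string", search_string])
    return rows


def export_report(
    result: ClassificationResult,
    fmt: str,
    path: PathLike,
    search_string: str = "",
) -> Path:
    """Write a classification report as ``tsv`` or ``xlsx``.

    Both formats carry identical cell content; the points column always
    reconciles with ``total_points`` (no re-computation happens here).
    """
    path = Path(path)
    rows = _report_rows(result, search_string)
    if fmt == "tsv":
        text = "\n".join("\t".join(cell for cell in row) for row in rows) + "\n"
        path.write_text(text, encoding="utf-8")
    elif fmt == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = (result.variant_key or "variant").replace(":", "_")[:31]
        for row in rows:
            ws.append([str(c) for c in row])
        wb.save(path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def parse_report_tsv(path: PathLike) -> dict:
    """Parse a TSV report back into calls and summary (round-trip check)."""
    calls: list[dict] = []
    summary: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines:
        cells = line.split("\t")
        if not cells or not cells[0]:
            continue
        if cells[0] == "# variant":
            summary["variant"] = cells[1] if len(cells) > 1 else ""
        elif cells[0].startswith("## "):
            summary[cells[0][3:]] = cells[1] if len(cells) > 1 else ""
        elif cells[0] == "code":
            continue
        else:
            padded = cells + [""] * (len(_COLUMNS) - len(cells))
            calls.append(dict(zip(_COLUMNS, padded)))
    return {"calls": calls, "summary": summary}


# --------------------------------------------------------------------------
# single-variant and batch classification
# --------------------------------------------------------------------------

@dataclass
class RunLogEntry:
    variant_key: str
    started: str
    elapsed_s: float
    outcome: str  # classified | rejected | error
    message: str = ""


@dataclass
class SingleOutcome:
    status: str  # classified | rejected | error
    message: str = ""
    result: Optional[ClassificationResult] = None
    report_path: Optional[Path] = None


def classify_single(
    gene: str,
    transcript: str,
    cdna: str,
    evidence_path: PathLike,
    config_path: Optional[PathLike] = None,
    rules_path: Optional[PathLike] = None,
    report_path: Optional[PathLike] = None,
    report_format: str = "tsv",
) -> SingleOutcome:
    """Validate, evaluate and classify one variant, optionally writing a
    report. Unsupported variants are *rejected* (no report); schema and
    I/O problems are *errors*.
    """
    try:
        descriptor = parse_cdna_description(cdna, gene_symbol=gene,
                                            transcript_id=transcript)
    except HgvsParseError as exc:
        return SingleOutcome("error", f"parse error: {exc}")

    verdict = validate_supported_variant(descriptor)
    if not verdict.accepted:
        return SingleOutcome("rejected", verdict.reason)

    try:
        bundle = load_evidence_bundle(evidence_path)
        configs = load_gene_config(config_path)
        rules = load_exclusion_rules(rules_path)
        assay_table = load_assay_table()
    except (OSError, BundleSchemaError, ValueError) as exc:
        return SingleOutcome("error", str(exc))

    bundle = bundle.model_copy(update={
        "descriptor": descriptor.model_copy(update={
            "gene_symbol": gene, "transcript_id": transcript,
        })
    })
    cfg = config_for_gene(configs, gene)
    result = combine(bundle, cfg, rules, assay_table)
    search = build_search_string(bundle.descriptor, bundle.protein_change)

    written = None
    if report_path is not None:
        try:
            written = export_report(result, report_format, report_path, search)
        except OSError as exc:
            return SingleOutcome("error", f"cannot write report: {exc}",
                                 result=result)
    return SingleOutcome("classified", result=result, report_path=written)


@dataclass
class BatchSummary:
    classified: int = 0
    rejected: int = 0
    errored: int = 0
    log_path: Optional[Path] = None
    entries: list[RunLogEntry] = dc_field(default_factory=list)


def classify_batch(
    table_path: PathLike,
    out_dir: PathLike,
    config_path: Optional[PathLike] = None,
    rules_path: Optional[PathLike] = None,
    report_format: str = "tsv",
    log_dir: Optional[PathLike] = None,
) -> BatchSummary:
    """Sequentially classify every row of a batch table.

    The table is tab-delimited with a header row
    ``gene transcript cdna evidence_path``. Each invocation creates a
    fresh timestamped log with exactly one line per input row; a failing
    row is logged and skipped, never aborting the batch.
    """
    table = Path(table_path)
    if not table.is_file():
        raise FileNotFoundError(f"batch table not found: {table}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logs = Path(log_dir) if log_dir else out
    logs.mkdir(parents=True, exist_ok=True)

    stamp = datetime.now(timezone.utc).strftime("%Y%m%dT%H%M%S%f")
    log_path = logs / f"run_{stamp}.log"
    summary = BatchSummary(log_path=log_path)

    lines = table.read_text(encoding="utf-8").splitlines()
    body = [l for l in lines if l.strip() and not l.startswith("#")]
    if body and body[0].lower().startswith("gene\t"):
        body = body[1:]

    with open(log_path, "w", encoding="utf-8") as log:
        log.write("# started\tvariant_key\toutcome\telapsed_s\tmessage\n")
        for i, line in enumerate(body):
            started = datetime.now(timezone.utc).isoformat()
            t0 = time.perf_counter()
            cells = line.split("\t")
            if len(cells) < 4:
                key = f"row{i}"
                outcome, message = "error", "expected 4 tab-separated columns"
            else:
                gene, transcript, cdna, evidence = (c.strip() for c in cells[:4])
                key = f"{gene}:{transcript}:{cdna}"
                safe = "".join(ch if ch.isalnum() or ch in "._+-" else "_"
                               for ch in key)
                single = classify_single(
                    gene, transcript, cdna, evidence,
                    config_path=config_path, rules_path=rules_path,
                    report_path=out / f"{i:03d}_{safe}.{report_format}",
                    report_format=report_format,
                )
                outcome, message = single.status, single.message
                if single.status == "classified":
                    message = single.result.classification.value
            elapsed = time.perf_counter() - t0
            entry = RunLogEntry(key, started, elapsed, outcome, message)
            summary.entries.append(entry)
            if outcome == "classified":
                summary.classified += 1
            elif outcome == "rejected":
                summary.rejected += 1
            else:
                summary.errored += 1
            log.write(f"{started}\t{key}\t{outcome}\t{elapsed:.4f}\t{message}\n")
    return summary
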