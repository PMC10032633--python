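"""Minimal parser for the supported subset of HGVS coding-DNA nomenclature.

Supported forms: substitutions (``c.100A>T``), deletions, duplications,
insertions and single-anchor deletion-insertions up to 25 nt, with signed
intron offsets (``c.1137+1``) and UTR positions (``c.-15``, ``c.*20``).
Inversions and two-sided delins parse but are rejected by
:func:`validate_supported_variant`. This is deliberately not a full HGVS
implementation: nomenclature correction and genome-coordinate input are
out of scope.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .models import VariantDescriptor, VariantType

#: Longest insertion/deletion the engine will classify, in nucleotides.
MAX_INDEL_NT = 25


class HgvsParseError(ValueError):
    """Raised for a malformed coding-DNA description; names the bad token."""


class UnsupportedNomenclatureError(HgvsParseError):
    """Raised for nomenclature outside the coding-DNA grammar (e.g. 'p.')."""


_POS = r"(?P<{p}>[-*]?\d+)(?P<{o}>[+-]\d+)?"
_POS_A = _POS.format(p="pos_a", o="off_a")
_POS_B = _POS.format(p="pos_b", o="off_b")
_NT = "[ACGTacgt]"

_PATTERNS = [
    (VariantType.SUBSTITUTION,
     re.compile(rf"^{_POS_A}(?P<ref>{_NT})>(?P<alt>{_NT})$")),
    (VariantType.DELINS,
     re.compile(rf"^{_POS_A}(?:_{_POS_B})?delins(?P<ins>{_NT}+)$")),
    (VariantType.DELETION,
     re.compile(rf"^{_POS_A}(?:_{_POS_B})?del(?P<seq>{_NT}*)$")),
    (VariantType.DUPLICATION,
     re.compile(rf"^{_POS_A}(?:_{_POS_B})?dup(?P<seq>{_NT}*)$")),
    (VariantType.INSERTION,
     re.compile(rf"^{_POS_A}_{_POS_B}ins(?P<ins>{_NT}+)$")),
    (VariantType.INVERSION,
     re.compile(rf"^{_POS_A}_{_POS_B}inv$")),
]


def _parse_pos(pos: str, off: Optional[str]) -> tuple[int, int, bool]:
    """Return (coding position, intron offset, is-3'UTR)."""
    utr3 = pos.startswith("*")
    value = int(pos[1:]) if utr3 else int(pos)
    offset = int(off) if off else 0
    return value, offset, utr3


def parse_cdna_description(
    cdna: str,
    gene_symbol: str = "",
    transcript_id: str = "",
) -> VariantDescriptor:
    """Parse a coding-DNA variant description into a :class:`VariantDescriptor`.

    Raises :class:`UnsupportedNomenclatureError` for protein-level ('p.')
    input and :class:`HgvsParseError` for anything the grammar does not
    cover, naming the offending token.
    """
    text = cdna.strip()
    if not text:
        raise HgvsParseError("empty variant description")
    if text.startswith("p."):
        raise UnsupportedNomenclatureError(
            f"protein-level nomenclature not supported: {text!r}; provide a 'c.' description"
        )
    if not text.startswith("c."):
        raise HgvsParseError(f"expected a description starting with 'c.', got {text!r}")
    body = text[2:]

    for vtype, pattern in _PATTERNS:
        m = pattern.match(body)
        if m is None:
            continue
        start, off_start, utr3_s = _parse_pos(m.group("pos_a"), m.group("off_a"))
        if m.groupdict().get("pos_b"):
            end, off_end, utr3_e = _parse_pos(m.group("pos_b"), m.group("off_b"))
        else:
            end, off_end, utr3_e = start, off_start, utr3_s

        ref, alt, length = "", "", 0
        span = _span_length(start, end, utr3_s, utr3_e, off_start, off_end)
        if vtype is VariantType.SUBSTITUTION:
            ref = m.group("ref").upper()
            alt = m.group("alt").upper()
        elif vtype is VariantType.DELETION:
            seq = m.group("seq").upper()
            ref = seq
            length = len(seq) if seq else span
            if seq and span is not None and len(seq) != span:
                raise HgvsParseError(
                    f"deleted sequence length {len(seq)} does not match span {span} in {text!r}"
                )
        elif vtype is VariantType.DUPLICATION:
            seq = m.group("seq").upper()
            alt = seq
            length = len(seq) if seq else span
            if seq and span is not None and len(seq) != span:
                raise HgvsParseError(
                    f"duplicated sequence length {len(seq)} does not match span {span} in {text!r}"
                )
        elif vtype is VariantType.INSERTION:
            alt = m.group("ins").upper()
            length = len(alt)
        elif vtype is VariantType.DELINS:
            alt = m.group("ins").upper()
            # deleted side length (validation rejects two-sided delins)
            length = max(len(alt), span or 1)
        elif vtype is VariantType.INVERSION:
            length = span or 0

        if length is None:
            raise HgvsParseError(
                f"cannot determine indel length for {text!r} (intron-spanning range without sequence)"
            )

        try:
            return VariantDescriptor(
                gene_symbol=gene_symbol,
                transcript_id=transcript_id,
                cdna=text,
                variant_type=vtype,
                cdna_start=start,
                cdna_end=end,
                intron_offset_start=off_start,
                intron_offset_end=off_end,
                ref_allele=ref,
                alt_allele=alt,
                indel_length=length,
                utr3_start=utr3_s,
                utr3_end=utr3_e,
            )
        except ValueError as exc:
            raise HgvsParseError(f"invalid description {text!r}: {exc}") from exc

    raise HgvsParseError(f"unrecognized coding-DNA description: {text!r}")


def _span_length(start, end, utr3_s, utr3_e, off_s, off_e) -> Optional[int]:
    """Nucleotide span of a position range, or None when it is not computable
    in pure cDNA coordinates (range crossing an intron or a UTR boundary)."""
    if utr3_s != utr3_e:
        return None
    if off_s == off_e:
        return end - start + 1
    if start == end:  # both positions hang off the same coding anchor
        return abs(off_e - off_s) + 1
    return None


def format_cdna(d: VariantDescriptor) -> str:
    """Format a descriptor back to its coding-DNA string (parse inverse)."""

    def pos(p: int, off: int, utr3: bool) -> str:
        base = f"*{p}" if utr3 else str(p)
        return f"{base}{off:+d}" if off else base

    a = pos(d.cdna_start, d.intron_offset_start, d.utr3_start)
    b = pos(d.cdna_end, d.intron_offset_end, d.utr3_end)
    rng = a if a == b else f"{a}_{b}"
    t = d.variant_type
    if t is VariantType.SUBSTITUTION:
        return f"c.{a}{d.ref_allele}>{d.alt_allele}"
    if t is VariantType.DELETION:
        return f"c.{rng}del{d.ref_allele}"
    if t is VariantType.DUPLICATION:
        return f"c.{rng}dup{d.alt_allele}"
    if t is VariantType.INSERTION:
        return f"c.{rng}ins{d.alt_allele}"
    if t is VariantType.DELINS:
        return f"c.{rng}delins{d.alt_allele}"
    if t is VariantType.INVERSION:
        return f"c.{rng}inv"
    raise ValueError(f"unknown variant type {t}")


@dataclass
class ValidationVerdict:
    accepted: bool
    reason: str = ""  # machine-readable token when rejected


def validate_supported_variant(d: VariantDescriptor) -> ValidationVerdict:
    """Total function deciding whether the engine supports this variant.

    Rejections: inversions, deletion-insertions replacing more than one
    nucleotide, and insertions/deletions longer than 25 nt.
    """
    if d.variant_type is VariantType.INVERSION:
        return ValidationVerdict(False, "inversion_unsupported")
    if d.variant_type is VariantType.DELINS:
        span = _span_length(
            d.cdna_start, d.cdna_end, d.utr3_start, d.utr3_end,
            d.intron_offset_start, d.intron_offset_end,
        )
        if span is None or span > 1:
            return ValidationVerdict(False, "delins_both_sides_gt1")
    if d.indel_length > MAX_INDEL_NT:
        return ValidationVerdict(False, f"indel length exceeds {MAX_INDEL_NT}")
    return ValidationVerdict(True)
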