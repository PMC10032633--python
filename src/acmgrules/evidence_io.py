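"""Loading and validation of evidence bundles and gene configuration.

An *evidence bundle* is one JSON document holding everything the engine
needs for a variant (see :class:`~acmgrules.models.EvidenceBundle`). The
JSON schema of the bundle is shipped with the package
(``resources/evidence_bundle.schema.json``) and regenerated from the
pydantic model.

The *gene configuration* file is tab-delimited text with three columns
(``gene``, ``parameter``, ``value``), one parameter per row, UTF-8, with
``#`` comments. User rows override shipped defaults; genes without rows
inherit the GENERAL configuration.
"""
from __future__ import annotations

import dataclasses
import json
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional, Union

from pydantic import ValidationError

from .models import (
    GENERAL,
    MMR_GENES,
    EvidenceBundle,
    GeneConfig,
    Strength,
)

PathLike = Union[str, Path]


class BundleSchemaError(ValueError):
    """Evidence-bundle JSON failed validation; lists every failing field path."""

    def __init__(self, errors: list[str]):
        self.field_errors = errors
        super().__init__(
            "evidence bundle failed schema validation:\n  " + "\n  ".join(errors)
        )


class ConfigError(ValueError):
    """Gene-configuration file is malformed or violates threshold ordering."""


# --------------------------------------------------------------------------
# evidence bundles
# --------------------------------------------------------------------------

def load_evidence_bundle(path: PathLike) -> EvidenceBundle:
    """Load and validate one evidence-bundle JSON file.

    Optional evidence absent from the file stays explicitly missing
    (``None``); it is never defaulted to zero.
    """
    raw = Path(path).read_text(encoding="utf-8")
    return parse_evidence_bundle(raw)


def parse_evidence_bundle(raw_json: str) -> EvidenceBundle:
    try:
        return EvidenceBundle.model_validate_json(raw_json)
    except ValidationError as exc:
        paths = [
            ".".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        ]
        raise BundleSchemaError(paths) from exc


def write_evidence_bundle(bundle: EvidenceBundle, path: PathLike) -> None:
    Path(path).write_text(dump_evidence_bundle(bundle), encoding="utf-8")


def dump_evidence_bundle(bundle: EvidenceBundle) -> str:
    """Serialize to the canonical JSON form (sorted keys, 2-space indent).

    ``load . dump`` is the identity on canonical form.
    """
    payload = bundle.model_dump(mode="json", exclude_none=True)
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def bundle_json_schema() -> dict:
    """The evidence-bundle JSON schema, derived from the pydantic model."""
    return EvidenceBundle.model_json_schema()


def shipped_schema_path() -> Path:
    return Path(
        importlib_resources.files("acmgrules.resources") / "evidence_bundle.schema.json"
    )


# --------------------------------------------------------------------------
# gene configuration
# --------------------------------------------------------------------------

_BOOL_TRUE = {"true", "1", "yes", "y"}
_BOOL_FALSE = {"false", "0", "no", "n"}


def _coerce(name: str, value: str, field_type) -> object:
    text = value.strip()
    if field_type is bool:
        low = text.lower()
        if low in _BOOL_TRUE:
            return True
        if low in _BOOL_FALSE:
            return False
        raise ConfigError(f"parameter {name!r}: expected boolean, got {text!r}")
    if field_type is float:
        return float(text)
    if field_type is int:
        return int(text)
    if field_type is Strength:
        return Strength(text)
    if field_type is str:
        return text
    # Optional[int] and friends
    if text.lower() in ("none", ""):
        return None
    try:
        return int(text)
    except ValueError:
        return text


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(GeneConfig)}
_PY_TYPES = {
    "float": float, "int": int, "bool": bool, "str": str,
    "Strength": Strength, "Optional[int]": object,
}


def _field_type(name: str):
    t = _FIELD_TYPES[name]
    if isinstance(t, str):
        return _PY_TYPES.get(t, object)
    return t


def default_gene_configs() -> dict[str, GeneConfig]:
    """Shipped per-gene configurations for the nine hereditary-cancer genes
    with gene-specific guidelines, plus the GENERAL fallback.

    Numeric frequency thresholds are explicit shipped defaults intended for
    curator review; the rule-variant switches (PVS1 mode, PS1/PM5 mode,
    BS2/BP2 modes, PM1/PP2 applicability) encode the gene-specific
    guideline structure.
    """
    configs: dict[str, GeneConfig] = {}

    # PM2 is kept at supporting strength for the general ruleset, in line
    # with current practice of demoting absence-from-controls evidence.
    configs[GENERAL] = GeneConfig(gene_symbol=GENERAL, pm2_strength=Strength.SUPPORTING)

    configs["ATM"] = GeneConfig(
        gene_symbol="ATM",
        pm1_applicable=False,
        bs2_mode="off",
    )
    configs["CDH1"] = GeneConfig(
        gene_symbol="CDH1",
        pm2_strength=Strength.SUPPORTING,
        pvs1_mode="cdh1_site_specific",
        ps1_enabled=False,
        pm5_mode="cdh1_truncating",
        bs2_mode="not_automated",
        bp2_mode="homozygote_supporting",
        bp7_requires_nonconserved=False,
        pm1_applicable=False,
        ps3_bs3_covered=False,
    )
    configs["CHEK2"] = GeneConfig(
        gene_symbol="CHEK2",
        bs2_mode="off",
    )
    for gene in MMR_GENES:
        configs[gene] = GeneConfig(
            gene_symbol=gene,
            mmr_splice_combination=True,
            pm1_applicable=False,
            bs2_mode="not_automated",
            bp2_mode="not_applicable",
            ps3_bs3_covered=(gene != "PMS2"),
        )
    configs["PTEN"] = GeneConfig(
        gene_symbol="PTEN",
        pvs1_mode="pten_override",
        pvs1_override_boundary=1121,
        pp2_enabled=True,
        bs3_covered=False,
    )
    configs["TP53"] = GeneConfig(
        gene_symbol="TP53",
    )

    for cfg in configs.values():
        cfg.validate()
    return configs


def load_gene_config(
    path: Optional[PathLike] = None,
    defaults: Optional[dict[str, GeneConfig]] = None,
) -> dict[str, GeneConfig]:
    """Load gene configurations, applying user overrides on shipped defaults.

    ``path`` is a 3-column tab-delimited file (gene, parameter, value);
    ``None`` or an empty file returns the shipped defaults. Unknown genes
    are allowed: they start from a copy of GENERAL. Returned configs are
    re-validated; a threshold-ordering violation raises
    :class:`ConfigError` naming the gene and parameters.
    """
    configs = {
        gene: dataclasses.replace(cfg)
        for gene, cfg in (defaults or default_gene_configs()).items()
    }

    if path is not None:
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split("\t")
            if len(parts) != 3:
                raise ConfigError(
                    f"line {lineno}: expected 3 tab-separated columns "
                    f"(gene, parameter, value), got {len(parts)}"
                )
            gene, parameter, value = (p.strip() for p in parts)
            if gene.lower() == "gene" and parameter.lower() == "parameter":
                continue  # header row
            if parameter not in _FIELD_TYPES or parameter in (
                "gene_symbol", "applicability",
            ):
                raise ConfigError(f"line {lineno}: unknown parameter {parameter!r}")
            if gene not in configs:
                base = dataclasses.replace(configs[GENERAL])
                base.gene_symbol = gene
                configs[gene] = base
            try:
                coerced = _coerce(parameter, value, _field_type(parameter))
            except (ValueError, KeyError) as exc:
                raise ConfigError(f"line {lineno}: {exc}") from exc
            setattr(configs[gene], parameter, coerced)

    for gene, cfg in configs.items():
        try:
            cfg.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
    return configs


def config_for_gene(configs: dict[str, GeneConfig], gene: str) -> GeneConfig:
    """The configuration for ``gene``, falling back to GENERAL."""
    if gene in configs:
        return configs[gene]
    cfg = dataclasses.replace(configs[GENERAL])
    cfg.gene_symbol = gene
    return cfg
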