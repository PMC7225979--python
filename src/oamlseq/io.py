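"""File formats and configuration.

The canonical interchange format is a fixed-column TSV dialect (UTF-8,
"." for missing). A VCF v4.2 subset is supported as an import convenience:
per-sample tags ``AD`` (ref,alt depths) and ``DPF4``
(var_fwd,var_rev,ref_fwd,ref_rev), INFO fields ``GENE``, ``IMPACT``,
``CSQCLASS``, ``KNOWN`` (flag), ``HPLEN``, optional ``STYPE``. Gene models
use BED (0-based half-open); pathways a GMT-like format; survival records
a four-column TSV. All readers fail fast on malformed input, naming the
offending line.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .filters import FilterConfig
from .model import CoveragePair, GeneModel, SurvivalRecord, VariantCall

__all__ = [
    "VARIANT_COLUMNS",
    "read_variants", "write_variants",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
    "read_survival", "write_survival",
    "read_coverage", "write_coverage",
    "write_cohort",
    "PipelineConfig", "load_pipeline_config",
    "atomic_write_text", "write_frame",
]

VARIANT_COLUMNS = [
    "patient_id", "sample_id", "sample_type", "gene", "chrom", "pos",
    "ref", "alt", "impact", "consequence", "var_fwd", "var_rev",
    "ref_fwd", "ref_rev", "vaf", "quality", "known_variant",
    "homopolymer_len",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` atomically (tmp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_frame(frame: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, frame.to_csv(sep="\t", index=False, na_rep="."))


# ---------------------------------------------------------------- variants

def write_variants(calls: Iterable[VariantCall], path: str | Path) -> None:
    rows = [{col: getattr(c, col) for col in VARIANT_COLUMNS} for c in calls]
    frame = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    frame["known_variant"] = frame["known_variant"].map(
        lambda b: "true" if b else "false")
    atomic_write_text(path, frame.to_csv(sep="\t", index=False,
                                         float_format="%.17g"))


def _variants_from_tsv(path: Path) -> list[VariantCall]:
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=["."],
                        keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    calls = []
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            counts = {k: int(row[k]) for k in ("var_fwd", "var_rev",
                                               "ref_fwd", "ref_rev")}
            depth = sum(counts.values())
            vaf_raw = row["vaf"]
            if isinstance(vaf_raw, str) and vaf_raw != "":
                vaf = float(vaf_raw)
            elif depth > 0:  # VAF recomputed from counts when absent
                vaf = (counts["var_fwd"] + counts["var_rev"]) / depth
            else:
                raise ValueError("missing vaf and zero depth")
            calls.append(VariantCall(
                patient_id=row["patient_id"], sample_id=row["sample_id"],
                sample_type=row["sample_type"], gene=row["gene"],
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
                alt=row["alt"], impact=row["impact"],
                consequence=row["consequence"], vaf=vaf,
                quality=float(row["quality"] or 0.0),
                known_variant=str(row["known_variant"]).lower()
                in ("true", "1", "yes"),
                homopolymer_len=int(row["homopolymer_len"] or 0),
                **counts))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {line_no}: {exc}") from exc
    return calls


def _variants_from_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[VariantCall] = []
    for rec in vcf:
        info = dict(rec.INFO)
        for tag in ("GENE", "IMPACT", "CSQCLASS"):
            if tag not in info:
                raise ValueError(
                    f"{path}: record {rec.CHROM}:{rec.POS} missing INFO "
                    f"tag {tag}")
        try:
            dpf4 = rec.format("DPF4")
        except KeyError:
            dpf4 = None
        if dpf4 is None:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} missing FORMAT "
                f"tag DPF4")
        for si, sample in enumerate(samples):
            vf, vr, rf, rr = (int(x) for x in dpf4[si][:4])
            if vf < 0:  # missing for this sample
                continue
            depth = vf + vr + rf + rr
            vaf = (vf + vr) / depth if depth else 0.0
            calls.append(VariantCall(
                patient_id=sample, sample_id=sample,
                sample_type=str(info.get("STYPE", "ffpe")),
                gene=str(info["GENE"]), chrom=rec.CHROM, pos=rec.POS,
                ref=rec.REF, alt=rec.ALT[0], impact=str(info["IMPACT"]),
                consequence=str(info["CSQCLASS"]), var_fwd=vf, var_rev=vr,
                ref_fwd=rf, ref_rev=rr, vaf=vaf,
                quality=float(rec.QUAL or 0.0),
                known_variant=bool(info.get("KNOWN", False)),
                homopolymer_len=int(info.get("HPLEN", 0))))
    return calls


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Read variant calls from the TSV dialect or the VCF subset."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _variants_from_tsv(path)
    if dialect == "vcf":
        return _variants_from_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# -------------------------------------------------------------- gene models

def write_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    lines = [f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene}\t0\t{m.strand}"
             for m in models]
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> list[GeneModel]:
    models = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}, line {i}: expected >= 4 BED columns")
        try:
            models.append(GeneModel(
                gene=fields[3], chrom=fields[0], start=int(fields[1]),
                end=int(fields[2]),
                strand=fields[5] if len(fields) > 5 else "."))
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return models


# ----------------------------------------------------------------- pathways

def write_gmt(pathways: dict[str, set[str]], path: str | Path) -> None:
    lines = [f"{name}\t-\t" + "\t".join(sorted(genes))
             for name, genes in sorted(pathways.items())]
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    pathways: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}, line {i}: expected name, description, genes...")
        pathways[fields[0]] = set(fields[2:])
    return pathways


# ----------------------------------------------------------------- survival

def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [{"patient_id": r.patient_id, "endpoint": r.endpoint,
          "time": r.time, "event": int(r.event), "group": r.group or "."}
         for r in records],
        columns=["patient_id", "endpoint", "time", "event", "group"])
    atomic_write_text(path, frame.to_csv(sep="\t", index=False,
                                         float_format="%.17g"))


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["patient_id", "endpoint", "time", "event"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    records = []
    for idx, row in frame.iterrows():
        try:
            group = row.get("group", ".")
            records.append(SurvivalRecord(
                patient_id=row["patient_id"], endpoint=row["endpoint"],
                time=float(row["time"]), event=bool(int(row["event"])),
                group="" if group in (".", None) else str(group)))
        except ValueError as exc:
            raise ValueError(f"{path}, line {idx + 2}: {exc}") from exc
    return records


# ----------------------------------------------------------------- coverage

def write_coverage(pair: CoveragePair, path: str | Path) -> None:
    frame = pd.DataFrame({"gene": pair.genes, "tumor_cov": pair.tumor_cov,
                          "normal_cov": pair.normal_cov})
    atomic_write_text(path, frame.to_csv(sep="\t", index=False,
                                         float_format="%.17g"))


def read_coverage(path: str | Path, patient_id: str) -> CoveragePair:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "tumor_cov", "normal_cov")
               if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    return CoveragePair(patient_id, list(frame["gene"]),
                        frame["tumor_cov"].to_numpy(float),
                        frame["normal_cov"].to_numpy(float))


# ------------------------------------------------------------------- cohort

def write_cohort(cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort to a directory; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["variants"] = outdir / "variants.tsv"
    write_variants(cohort.calls, paths["variants"])
    paths["gene_models"] = outdir / "gene_models.bed"
    write_bed(cohort.gene_models, paths["gene_models"])
    paths["pathways"] = outdir / "pathways.gmt"
    write_gmt(cohort.pathways, paths["pathways"])
    paths["survival"] = outdir / "survival.tsv"
    write_survival(cohort.survival, paths["survival"])
    for pair in cohort.coverage_pairs:
        key = f"coverage_{pair.patient_id}"
        paths[key] = outdir / f"{key}.tsv"
        write_coverage(pair, paths[key])
    paths["truth"] = outdir / "truth.json"
    atomic_write_text(paths["truth"],
                      json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths


# ------------------------------------------------------------ configuration

@dataclass
class PipelineConfig:
    """Run configuration for the end-to-end pipeline.

    With ``simulate=True`` the input cohort is generated from the seed and
    written under ``outdir/cohort``; otherwise ``variants`` (and optionally
    coverage/pathway/survival paths) must point at existing files.
    """

    outdir: str = "results"
    seed: int = 0
    simulate: bool = True
    variants: str | None = None
    coverage: dict[str, str] = field(default_factory=dict)  # patient -> path
    pathways: str | None = None
    survival: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    gain_thresh: float = 0.3
    loss_thresh: float = -0.3
    enrichment_adjust: bool = True
    survival_gene: str = "JAK3"
    endpoint: str = "PFS"

    def config_hash(self) -> str:
        blob = json.dumps({**asdict(self)}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_FILTER_KEYS = {f for f in FilterConfig.__dataclass_fields__}
_PIPELINE_KEYS = {f for f in PipelineConfig.__dataclass_fields__}


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON pipeline config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _PIPELINE_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    fc_raw = raw.pop("filter_config", {}) or {}
    unknown = set(fc_raw) - _FILTER_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown filter keys {sorted(unknown)}")
    return PipelineConfig(filter_config=FilterConfig(**fc_raw), **raw)
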