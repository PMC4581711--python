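"""Readers and writers for the tabular formats and the association network.

TSV dialect: tab-separated, UTF-8, ``NA`` for missing, first column
``sample_id``.  Genotypes may alternatively come from a VCF (read-only,
``DS`` dosage when present, otherwise expected dose from ``GT``).
Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from trimetaqtl.datatypes import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    MetaboliteDef,
    MetabolitePanel,
    ProbeRecord,
    SnpRecord,
    ValidationError,
)

log = logging.getLogger(__name__)

_TSV = dict(sep="\t", na_values=["NA"], keep_default_na=False)


def _read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, **_TSV)
    if frame.columns[0] != "sample_id":
        raise ValidationError(f"{path}: first column must be 'sample_id'")
    frame = frame.set_index("sample_id")
    for col in frame.columns:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()
                             & frame[col].notna()]
            where = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"{path}: non-numeric cell at sample {where!r}, column {col!r}"
            ) from exc
    return frame


def _write_matrix_tsv(path: str | Path, sample_ids, columns, values) -> None:
    frame = pd.DataFrame(values, columns=columns)
    frame.insert(0, "sample_id", sample_ids)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_snp_annotation(path: str | Path) -> list[SnpRecord]:
    frame = pd.read_csv(path, **_TSV)
    required = {"snp_id", "chrom", "pos"}
    if not required <= set(frame.columns):
        raise ValidationError(f"{path}: needs columns {sorted(required)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SnpRecord(
                snp_id=str(row.snp_id), chrom=str(row.chrom), pos=int(row.pos),
                allele_ref=str(getattr(row, "allele_ref", "A")),
                allele_alt=str(getattr(row, "allele_alt", "G")),
                maf=float(getattr(row, "maf", np.nan)),
                info=float(getattr(row, "info", 1.0)),
            )
        )
    return records


def read_genotypes(
    path: str | Path, format: str = "tsv", annot_path: str | Path | None = None
) -> GenotypeMatrix:
    """Read a gene-dose matrix from TSV (+ sidecar SNP annotation) or VCF."""

    if format == "tsv":
        frame = _read_matrix_tsv(path)
        if annot_path is not None:
            snps = read_snp_annotation(annot_path)
            by_id = {s.snp_id: s for s in snps}
            missing = [c for c in frame.columns if c not in by_id]
            if missing:
                raise ValidationError(f"{path}: SNPs missing from annotation: {missing[:5]}")
            snps = [by_id[c] for c in frame.columns]
        else:
            snps = [SnpRecord(snp_id=c, chrom="NA", pos=1) for c in frame.columns]
        return GenotypeMatrix(list(frame.index.astype(str)), snps, frame.to_numpy(float))
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF support requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snps, cols = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).ravel()
        else:
            gt = np.asarray(var.genotypes)[:, :2]
            dose = np.where(gt < 0, np.nan, gt).sum(axis=1).astype(float)
        info = var.INFO.get("INFO", var.INFO.get("IMPINFO", 1.0))
        maf = var.INFO.get("MAF", np.nan)
        if not np.isfinite(maf):
            af = float(np.nanmean(dose)) / 2.0
            maf = min(af, 1 - af)
        snps.append(
            SnpRecord(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}", chrom=str(var.CHROM),
                pos=int(var.POS), allele_ref=var.REF, allele_alt=var.ALT[0] if var.ALT else ".",
                maf=float(maf), info=float(info),
            )
        )
        cols.append(dose)
    doses = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, snps, doses)


def write_genotypes(
    G: GenotypeMatrix, path: str | Path, annot_path: str | Path | None = None
) -> None:
    _write_matrix_tsv(path, G.sample_ids, G.snp_ids, G.doses)
    if annot_path is not None:
        pd.DataFrame(
            [
                {
                    "snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
                    "allele_ref": s.allele_ref, "allele_alt": s.allele_alt,
                    "maf": s.maf, "info": s.info,
                }
                for s in G.snps
            ]
        ).to_csv(annot_path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_probe_annotation(path: str | Path) -> list[ProbeRecord]:
    frame = pd.read_csv(path, **_TSV)
    return [
        ProbeRecord(
            probe_id=str(r.probe_id), gene_symbol=str(getattr(r, "gene", r.probe_id)),
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
        )
        for r in frame.itertuples(index=False)
    ]


def read_expression(path: str | Path, annot_path: str | Path) -> ExpressionMatrix:
    frame = _read_matrix_tsv(path)
    probes = read_probe_annotation(annot_path)
    by_id = {p.probe_id: p for p in probes}
    missing = [c for c in frame.columns if c not in by_id]
    if missing:
        raise ValidationError(f"{path}: probes missing from annotation: {missing[:5]}")
    probes = [by_id[c] for c in frame.columns]
    return ExpressionMatrix(list(frame.index.astype(str)), probes, frame.to_numpy(float))


def write_expression(
    E: ExpressionMatrix, path: str | Path, annot_path: str | Path | None = None
) -> None:
    _write_matrix_tsv(path, E.sample_ids, E.probe_ids, E.values)
    if annot_path is not None:
        pd.DataFrame(
            [
                {
                    "probe_id": p.probe_id, "chrom": p.chrom, "start": p.start,
                    "end": p.end, "gene": p.gene_symbol,
                }
                for p in E.probes
            ]
        ).to_csv(annot_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------

def _split(field: str) -> tuple[str, ...]:
    field = str(field).strip()
    if not field or field == "NA":
        return ()
    return tuple(x.strip() for x in field.split(",") if x.strip())


def read_metabolite_defs(path: str | Path) -> list[MetaboliteDef]:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype=str)
    defs = []
    for r in frame.itertuples(index=False):
        lod = getattr(r, "lod", "")
        defs.append(
            MetaboliteDef(
                name=str(r.name), kind=str(getattr(r, "kind", "raw")),
                numerator=_split(getattr(r, "numerator", "")),
                denominator=_split(getattr(r, "denominator", "")),
                lod=float(lod) if lod not in ("", "NA", None) else None,
            )
        )
    return defs


def read_metabolites(path: str | Path, defs_path: str | Path) -> MetabolitePanel:
    """Read a raw-scale metabolite panel; below-LOD flags derive from the
    per-metabolite LODs in the definitions file.  Derived (ratio/sum)
    definitions must reference known raw names."""

    frame = _read_matrix_tsv(path)
    defs = read_metabolite_defs(defs_path)
    raw_names = {d.name for d in defs if d.kind == "raw"}
    for d in defs:
        for comp in tuple(d.numerator) + tuple(d.denominator):
            if comp not in raw_names:
                raise ValidationError(f"{defs_path}: {d.name} references unknown raw {comp!r}")
    by_name = {d.name: d for d in defs}
    missing = [c for c in frame.columns if c not in by_name]
    if missing:
        raise ValidationError(f"{path}: metabolites missing from defs: {missing[:5]}")
    col_defs = [by_name[c] for c in frame.columns]
    values = frame.to_numpy(float)
    below = np.zeros_like(values, dtype=bool)
    for j, d in enumerate(col_defs):
        if d.lod is not None:
            below[:, j] = values[:, j] < d.lod
    return MetabolitePanel(list(frame.index.astype(str)), col_defs, values, below)


def write_metabolites(
    panel: MetabolitePanel, path: str | Path, defs_path: str | Path | None = None
) -> None:
    _write_matrix_tsv(path, panel.sample_ids, panel.names, panel.values)
    if defs_path is not None:
        pd.DataFrame(
            [
                {
                    "name": d.name, "kind": d.kind,
                    "numerator": ",".join(d.numerator),
                    "denominator": ",".join(d.denominator),
                    "lod": "" if d.lod is None else f"{d.lod:.12g}",
                }
                for d in panel.defs
            ]
        ).to_csv(defs_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def read_covariates(path: str | Path) -> CovariateTable:
    frame = _read_matrix_tsv(path)
    return CovariateTable(list(frame.index.astype(str)), frame.reset_index(drop=True))


def write_covariates(C: CovariateTable, path: str | Path) -> None:
    _write_matrix_tsv(path, C.sample_ids, C.columns, C.matrix())


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

NODE_ROLES = (
    "locus", "locus_with_triangle", "cis_gene", "trans_gene",
    "raw_metabolite", "metabolite_ratio",
)


def write_network(nodes, edges, path: str | Path, format: str = "graphml") -> None:
    """Write the association network.

    ``nodes``: iterable of (node_id, role) pairs or dicts with ``id``/``role``.
    ``edges``: dicts with ``u``, ``v``, ``explained_var``, ``layer``.  Edges
    referencing unknown nodes raise.
    """

    g = nx.Graph()
    for node in nodes:
        if isinstance(node, dict):
            nid, role = node["id"], node.get("role", "locus")
        else:
            nid, role = node
        g.add_node(str(nid), role=str(role))
    for e in edges:
        u, v = str(e["u"]), str(e["v"])
        if u not in g or v not in g:
            raise ValidationError(f"dangling edge {u!r}–{v!r}")
        g.add_edge(u, v, explained_var=float(e["explained_var"]),
                   layer=str(e.get("layer", "")))
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "json":
        payload = nx.node_link_data(g, edges="links")
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(str(path))
    if format == "json":
        payload = json.loads(Path(path).read_text())
        return nx.node_link_graph(payload, edges="links")
    raise ValueError(f"unknown network format {format!r}")
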