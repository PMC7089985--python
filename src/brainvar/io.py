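"""Readers and writers for the formats the pipeline touches.

Expression matrices travel as a genes x samples TSV plus a sample-metadata
CSV (a combined long-format TSV is auto-detected by header); genotypes as
VCF (via cyvcf2) or a long TSV; case-control genotype counts as a small
CSV; stage results as paired TSV + JSON reports.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationResult, GenotypeCounts2x3, HweResult
from .eqtl import EqtlDataset, EqtlRecord, EqtlScanResult, GenotypeDosage, dosage_encode
from .models import GeneticModel
from .trajectory import BrainExpressionDataset, PermutationResult, TrajectorySummary

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "read_expression_cube",
    "write_expression_cube",
    "read_counts_csv",
    "write_counts_csv",
    "write_report",
    "read_result_json",
]

_LONG_FORMAT_COLUMNS = {"sample_id", "donor_id", "region", "age", "age_unit", "gene", "rpkm"}


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_table(
    expr_path: str | Path, meta_path: str | Path | None = None
) -> BrainExpressionDataset:
    """Read an RPKM matrix TSV plus a metadata CSV into a dataset.

    The TSV has a ``gene`` column followed by one column per sample; the
    CSV has columns ``sample_id, donor_id, region, age, age_unit``.  When
    ``meta_path`` is omitted and the TSV header matches the combined
    long format (``sample_id, donor_id, region, age, age_unit, gene,
    rpkm``), that single file is accepted instead.
    """
    expr_path = Path(expr_path)
    head = pd.read_csv(expr_path, sep="\t", nrows=0)
    if meta_path is None:
        if not _LONG_FORMAT_COLUMNS <= set(head.columns):
            raise ValueError(
                "no metadata file given and the TSV is not in the combined "
                f"long format (needs columns {sorted(_LONG_FORMAT_COLUMNS)})"
            )
        long = pd.read_csv(expr_path, sep="\t")
        meta = (
            long[["sample_id", "donor_id", "region", "age", "age_unit"]]
            .drop_duplicates("sample_id")
            .reset_index(drop=True)
        )
        values = long.pivot(index="gene", columns="sample_id", values="rpkm")
        values.index.name = None
        values.columns.name = None
        return BrainExpressionDataset(meta=meta, values=values)

    expr = pd.read_csv(expr_path, sep="\t")
    if "gene" not in expr.columns:
        raise ValueError(f"{expr_path}: first column of the expression TSV must be 'gene'")
    values = expr.set_index("gene")
    values.index.name = None
    meta = pd.read_csv(meta_path)
    return BrainExpressionDataset(meta=meta, values=values)


def write_expression_table(
    dataset: BrainExpressionDataset, expr_path: str | Path, meta_path: str | Path
) -> None:
    """Write a dataset to the matrix TSV + metadata CSV pair."""
    out = dataset.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(expr_path, sep="\t", index=False, float_format="%.17g")
    dataset.meta.to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# Genotypes


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read genotype calls from a VCF (``.vcf``) or long TSV.

    Returns a DataFrame with columns ``individual_id, snp_id, allele1,
    allele2`` (None = missing call), one row per individual per SNP.
    Multi-allelic VCF records are skipped with a warning; malformed GT
    fields are an error.  TSV and VCF encodings of the same calls yield
    identical tables.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"individual_id", "snp_id", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: genotype TSV needs columns {sorted(required)}")
    for col in ("allele1", "allele2"):
        df[col] = df[col].map(lambda v: None if v in ("", ".", "NA") else v)
    return df[["individual_id", "snp_id", "allele1", "allele2"]]


def _read_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {variant.ID or variant.POS}",
                stacklevel=2,
            )
            continue
        alleles = [variant.REF, variant.ALT[0]]
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        for sample, gt in zip(samples, variant.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 not in (-1, 0, 1) or a2 not in (-1, 0, 1):
                raise ValueError(f"malformed GT for {sample} at {snp_id}")
            rows.append(
                {
                    "individual_id": sample,
                    "snp_id": snp_id,
                    "allele1": None if a1 == -1 else alleles[a1],
                    "allele2": None if a2 == -1 else alleles[a2],
                }
            )
    return pd.DataFrame(rows, columns=["individual_id", "snp_id", "allele1", "allele2"])


def write_genotypes_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    for col in ("allele1", "allele2"):
        out[col] = out[col].map(lambda v: "." if v is None else v)
    out.to_csv(path, sep="\t", index=False)


def write_vcf(
    dosage: GenotypeDosage,
    individuals: list[str],
    path: str | Path,
    chrom: str = "3",
    pos: int = 52_800_000,
) -> None:
    """Write one SNP's dosages as a minimal VCF v4.2 text file.

    REF is the major and ALT the minor allele; dosage is the ALT count.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    fields = [
        chrom,
        str(pos),
        dosage.snp_id or ".",
        dosage.major_allele,
        dosage.minor_allele,
        ".",
        "PASS",
        ".",
        "GT",
    ]
    gts = ["./." if math.isnan(d) else gt_map[d] for d in dosage.dosage]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(individuals) + "\n")
        fh.write("\t".join(fields + gts) + "\n")


# ---------------------------------------------------------------------------
# Expression cube (eQTL panel)


def write_expression_cube(dataset: EqtlDataset, path: str | Path) -> None:
    """Write the region x gene x individual cube as a long TSV."""
    rows = []
    for i, region in enumerate(dataset.regions):
        for j, gene in enumerate(dataset.genes):
            for k, ind in enumerate(dataset.individuals):
                v = dataset.expression[i, j, k]
                if not math.isnan(v):
                    rows.append((ind, region, gene, v))
    pd.DataFrame(rows, columns=["individual_id", "region", "gene", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_expression_cube(path: str | Path, genotypes: pd.DataFrame) -> EqtlDataset:
    """Assemble an :class:`EqtlDataset` from a long expression TSV + calls.

    ``genotypes`` is a calls table as returned by :func:`read_genotypes`;
    every SNP in it is dosage-encoded against the cube's individuals.
    Individuals appear in the order of first appearance in the cube file;
    expression cells absent from the file are NaN.
    """
    long = pd.read_csv(path, sep="\t")
    required = {"individual_id", "region", "gene", "value"}
    if not required <= set(long.columns):
        raise ValueError(f"{path}: expression cube TSV needs columns {sorted(required)}")
    individuals = list(dict.fromkeys(long["individual_id"]))
    regions = list(dict.fromkeys(long["region"]))
    genes = list(dict.fromkeys(long["gene"]))
    cube = np.full((len(regions), len(genes), len(individuals)), np.nan)
    ri = {r: i for i, r in enumerate(regions)}
    gi = {g: i for i, g in enumerate(genes)}
    ii = {s: i for i, s in enumerate(individuals)}
    for ind, region, gene, value in long.itertuples(index=False):
        cube[ri[region], gi[gene], ii[ind]] = value
    dosages = {}
    for snp_id, group in genotypes.groupby("snp_id", sort=False):
        calls = group.set_index("individual_id").reindex(individuals)
        dosages[str(snp_id)] = dosage_encode(calls, snp_id=str(snp_id))
    return EqtlDataset(
        individuals=individuals,
        regions=regions,
        genes=genes,
        expression=cube,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# Case-control counts


def read_counts_csv(path: str | Path) -> GenotypeCounts2x3:
    """Read a ``genotype,case,control`` CSV with rows MM, Mm, mm."""
    df = pd.read_csv(path)
    required = {"genotype", "case", "control"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: counts CSV needs columns {sorted(required)}")
    df = df.set_index("genotype")
    missing = [g for g in ("MM", "Mm", "mm") if g not in df.index]
    if missing:
        raise ValueError(f"{path}: missing genotype rows: {missing}")
    vals = {}
    for g in ("MM", "Mm", "mm"):
        for grp in ("case", "control"):
            v = df.loc[g, grp]
            if float(v) != int(v) or int(v) < 0:
                raise ValueError(f"{path}: count for {g}/{grp} must be a nonnegative integer")
            vals[(g, grp)] = int(v)
    return GenotypeCounts2x3(
        case_MM=vals[("MM", "case")],
        case_Mm=vals[("Mm", "case")],
        case_mm=vals[("mm", "case")],
        ctrl_MM=vals[("MM", "control")],
        ctrl_Mm=vals[("Mm", "control")],
        ctrl_mm=vals[("mm", "control")],
    )


def write_counts_csv(counts: GenotypeCounts2x3, path: str | Path) -> None:
    pd.DataFrame(
        {
            "genotype": ["MM", "Mm", "mm"],
            "case": [counts.case_MM, counts.case_Mm, counts.case_mm],
            "control": [counts.ctrl_MM, counts.ctrl_Mm, counts.ctrl_mm],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reports


def _float(v):
    return float(v) if isinstance(v, (np.floating, np.integer)) else v


def _assoc_row(r: AssociationResult) -> dict:
    return {
        "or1_ori": r.or1_ori,
        "or2_ori": r.or2_ori,
        "model": r.selected_model.value,
        "or": r.or_step3,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "p": r.p_value,
        "or1_mod": r.or1_mod,
        "or2_mod": r.or2_mod,
    }


def write_report(result, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a stage result as ``<prefix>.tsv`` + ``<prefix>.json``.

    Column order is deterministic and floats keep full precision (17
    significant digits); the JSON mirrors the TSV content and, for results
    with nested structure, carries everything needed to rebuild the object
    (see :func:`read_result_json`).
    """
    tsv_path = Path(f"{out_prefix}.tsv")
    json_path = Path(f"{out_prefix}.json")

    if isinstance(result, AssociationResult):
        table = pd.DataFrame([_assoc_row(result)])
        payload = {
            "kind": "association",
            **_assoc_row(result),
            "alpha": result.alpha,
            "near_null": result.near_null,
            "hwe_ok": result.hwe_ok,
            "flags": list(result.flags),
            "hwe": dataclasses.asdict(result.hwe),
            "counts": dataclasses.asdict(result.counts),
            "model_distances": {m.value: d for m, d in result.model_distances.items()},
        }
    elif isinstance(result, EqtlScanResult):
        cols = [
            "snp_id", "region", "gene", "n_used", "slope", "se",
            "t_statistic", "p_value", "n0", "n1", "n2", "raising_allele", "significant",
        ]
        rows = []
        for rec in result.records:
            n0, n1, n2 = rec.genotype_class_counts
            rows.append(
                dict(
                    zip(
                        cols,
                        [
                            rec.snp_id, rec.region, rec.gene, rec.n_used, rec.slope,
                            rec.se, rec.t_statistic, rec.p_value, n0, n1, n2,
                            rec.raising_allele, rec.p_value < result.threshold,
                        ],
                    )
                )
            )
        table = pd.DataFrame(rows, columns=cols)
        payload = {
            "kind": "eqtl_scan",
            "snp_id": result.snp_id,
            "alpha": result.alpha,
            "threshold": result.threshold,
            "n_regions": result.n_regions,
            "n_genes": result.n_genes,
            "untestable": [list(p) for p in result.untestable],
            "records": rows,
        }
    elif isinstance(result, PermutationResult):
        payload = {"kind": "permutation", **dataclasses.asdict(result)}
        table = pd.DataFrame([{k: v for k, v in payload.items() if k != "kind"}])
    elif isinstance(result, TrajectorySummary):
        table = result.table
        payload = {
            "kind": "trajectory_summary",
            "gene": result.gene,
            "grand_mean": result.grand_mean,
            "n_retained": result.n_retained,
            "n_dropped": result.n_dropped,
            "table": result.table.to_dict(orient="records"),
        }
    else:
        raise TypeError(f"no report writer for {type(result).__name__}")

    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_float)
        fh.write("\n")
    return tsv_path, json_path


def read_result_json(path: str | Path):
    """Rebuild a stage result object from its JSON report."""
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.get("kind")
    if kind == "association":
        counts = GenotypeCounts2x3(**payload["counts"])
        hwe_raw = payload["hwe"]
        hwe = HweResult(
            chi2=hwe_raw["chi2"],
            p_value=hwe_raw["p_value"],
            observed=tuple(hwe_raw["observed"]),
            expected=tuple(hwe_raw["expected"]),
            allele_freq=hwe_raw["allele_freq"],
        )
        return AssociationResult(
            counts=counts,
            hwe=hwe,
            hwe_ok=payload["hwe_ok"],
            or1_ori=payload["or1_ori"],
            or2_ori=payload["or2_ori"],
            selected_model=GeneticModel(payload["model"]),
            model_distances={
                GeneticModel(m): d for m, d in payload["model_distances"].items()
            },
            near_null=payload["near_null"],
            or_step3=payload["or"],
            ci_low=payload["ci_low"],
            ci_high=payload["ci_high"],
            p_value=payload["p"],
            or1_mod=payload["or1_mod"],
            or2_mod=payload["or2_mod"],
            alpha=payload["alpha"],
            flags=tuple(payload["flags"]),
        )
    if kind == "eqtl_scan":
        records = tuple(
            EqtlRecord(
                snp_id=r["snp_id"],
                region=r["region"],
                gene=r["gene"],
                n_used=r["n_used"],
                slope=r["slope"],
                se=r["se"],
                t_statistic=r["t_statistic"],
                p_value=r["p_value"],
                genotype_class_counts=(r["n0"], r["n1"], r["n2"]),
                raising_allele=r["raising_allele"],
            )
            for r in payload["records"]
        )
        return EqtlScanResult(
            snp_id=payload["snp_id"],
            records=records,
            threshold=payload["threshold"],
            alpha=payload["alpha"],
            n_regions=payload["n_regions"],
            n_genes=payload["n_genes"],
            untestable=tuple(tuple(p) for p in payload["untestable"]),
        )
    if kind == "permutation":
        payload.pop("kind")
        return PermutationResult(**payload)
    raise ValueError(f"unknown result kind {kind!r} in {path}")
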