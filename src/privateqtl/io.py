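"""File formats: tab-delimited tables, VCF import, truth/provenance JSON.

All tables are UTF-8 TSV with ``NA`` for missing values and optional
``# key=value`` header comment lines carrying metadata (seeds,
thresholds, the log base of the size scale).  Genotype positions are
1-based; sex is coded F/M, diet fed/starved.  Floats round-trip at 12
significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import (
    INVERSION_CATALOGUE,
    FixedEffects,
    LineageCovariates,
    PanelGenotypes,
    PlantedEffect,
    SimTruth,
    VarianceComponents,
)

_FLOAT_FMT = "%.12g"


def _write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA",
                  float_format=_FLOAT_FMT)


def _read_table(path, **kwargs) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", na_values=["NA"], **kwargs)
    return df, meta


# ---------------------------------------------------------------- genotypes

_GENO_FIXED = ["marker_id", "chrom", "pos", "major", "minor"]


def write_genotypes(panel: PanelGenotypes, path, meta: dict | None = None) -> None:
    df = pd.DataFrame({
        "marker_id": panel.marker_ids,
        "chrom": panel.chrom,
        "pos": panel.pos,
        "major": panel.major_allele,
        "minor": panel.minor_allele,
    })
    calls = pd.DataFrame(panel.calls.T, columns=panel.lineage_ids)
    calls = calls.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df = pd.concat([df, calls], axis=1)
    _write_table(df, path, meta={"log_base": "e", **(meta or {})})


def read_genotypes(path) -> tuple[PanelGenotypes, dict]:
    """Load a genotype TSV; recompute MAF and normalize orientation.

    Returns the panel and a metadata dict including ``n_flipped``, the
    number of markers whose major/minor labels were swapped because the
    labelled minor class was the more frequent.
    """
    df, meta = _read_table(path, dtype={"chrom": str})
    missing = [c for c in _GENO_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"malformed genotype header: missing {missing}")
    if df["marker_id"].duplicated().any():
        dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValueError(f"duplicate marker ids: {dups[:5]}")
    lineage_ids = [c for c in df.columns if c not in _GENO_FIXED]
    calls = df[lineage_ids].to_numpy(float).T
    panel = PanelGenotypes(
        lineage_ids=lineage_ids,
        marker_ids=df["marker_id"].tolist(),
        chrom=df["chrom"].to_numpy(str),
        pos=df["pos"].to_numpy(int),
        major_allele=df["major"].to_numpy(str),
        minor_allele=df["minor"].to_numpy(str),
        calls=calls,
    )
    meta["n_flipped"] = panel.normalize_orientation()
    return panel, meta


def read_genotypes_vcf(path) -> tuple[PanelGenotypes, dict]:
    """Import homozygous diploid calls from a VCF.

    0/0 maps to 0, 1/1 to 2, ./. to missing.  Records with any
    heterozygous call, or with more than one ALT allele, are rejected
    and counted in the returned metadata.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires cyvcf2") from exc
    vcf = VCF(str(path))
    lineage_ids = list(vcf.samples)
    rows, chrom, pos, major, minor, marker_ids = [], [], [], [], [], []
    n_rejected = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_rejected += 1
            continue
        calls = np.full(len(lineage_ids), np.nan)
        het = False
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            if a != b:
                het = True
                break
            calls[i] = 0.0 if a == 0 else 2.0
        if het:
            n_rejected += 1
            continue
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}_SNP")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        major.append(var.REF)
        minor.append(var.ALT[0])
        rows.append(calls)
    panel = PanelGenotypes(
        lineage_ids=lineage_ids, marker_ids=marker_ids,
        chrom=np.array(chrom), pos=np.array(pos, int),
        major_allele=np.array(major), minor_allele=np.array(minor),
        calls=np.array(rows).T if rows else np.empty((len(lineage_ids), 0)),
    )
    meta = {"n_rejected": n_rejected, "n_flipped": panel.normalize_orientation()}
    return panel, meta


# --------------------------------------------------------------- covariates

def write_covariates(cov: LineageCovariates, path, meta=None) -> None:
    _write_table(cov.as_frame().reset_index(), path, meta)


def read_covariates(path) -> tuple[LineageCovariates, dict]:
    df, meta = _read_table(path)
    df = df.set_index("lineage_id")
    inv_cols = [c for c in df.columns if c in INVERSION_CATALOGUE]
    pc_cols = sorted((c for c in df.columns if c.startswith("pc")),
                     key=lambda c: int(c[2:]))
    cov = LineageCovariates(
        lineage_ids=[str(x) for x in df.index],
        wolbachia=df["wolbachia"].to_numpy(int),
        inversions=df[inv_cols].astype(int),
        pcs=df[pc_cols].to_numpy(float) if pc_cols else np.empty((len(df), 0)),
    )
    return cov, meta


# -------------------------------------------------------------- individuals

def write_individuals(records: pd.DataFrame, path, meta=None) -> None:
    _write_table(records[["lineage_id", "sex", "diet", "block", "size_log"]],
                 path, meta={"log_base": "e", **(meta or {})})


def read_individuals(path) -> tuple[pd.DataFrame, dict]:
    df, meta = _read_table(path, dtype={"lineage_id": str, "block": str})
    required = {"lineage_id", "sex", "diet", "block", "size_log"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"individuals table missing columns {sorted(missing)}")
    bad_sex = set(df["sex"]) - {"F", "M"}
    bad_diet = set(df["diet"]) - {"fed", "starved"}
    if bad_sex or bad_diet:
        raise ValueError(f"unknown levels: sex={bad_sex}, diet={bad_diet}")
    return df, meta


# ------------------------------------------------------------------- truth

def write_truth(truth: SimTruth, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)


def read_truth(path) -> SimTruth:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return SimTruth(
        planted_effects=[PlantedEffect(**e) for e in d["planted_effects"]],
        fixed_effects=FixedEffects(**d["fixed_effects"]),
        variance_components=VarianceComponents(**d["variance_components"]),
        seed=d["seed"],
    )


# -------------------------------------------------------------- annotation

def write_annotation(annotation: pd.DataFrame, path, meta=None) -> None:
    _write_table(annotation, path, meta)


def read_annotation(path) -> tuple[pd.DataFrame, dict]:
    df, meta = _read_table(path, dtype={"marker_id": str, "gene_id": str})
    required = {"marker_id", "gene_id", "site_class", "distance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns {sorted(missing)}")
    return df, meta


# --------------------------------------------------------------- gene sets

def write_gene_sets(sets: dict[str, list[str]], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, *genes]) + "\n")


def read_gene_sets(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                out[parts[0]] = [g for g in parts[1:] if g]
    return out


# -------------------------------------------------------------- provenance

def write_provenance(path, config: dict, counts: dict | None = None) -> None:
    import numpy
    import scipy

    from . import __version__
    doc = {
        "package": {"privateqtl": __version__, "numpy": numpy.__version__,
                    "scipy": scipy.__version__},
        "config": config,
        "counts": counts or {},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, default=str)


# ----------------------------------------------------------------- fixture

def write_fixture(outdir, panel, covariates, records, truth) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": str(outdir / "genotypes.tsv"),
        "covariates": str(outdir / "covariates.tsv"),
        "individuals": str(outdir / "individuals.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_genotypes(panel, paths["genotypes"], meta={"seed": truth.seed})
    write_covariates(covariates, paths["covariates"])
    write_individuals(records, paths["individuals"])
    write_truth(truth, paths["truth"])
    return paths


def read_fixture(outdir) -> tuple[PanelGenotypes, LineageCovariates,
                                  pd.DataFrame, SimTruth]:
    outdir = Path(outdir)
    panel, _ = read_genotypes(outdir / "genotypes.tsv")
    cov, _ = read_covariates(outdir / "covariates.tsv")
    records, _ = read_individuals(outdir / "individuals.tsv")
    truth = read_truth(outdir / "truth.json")
    return panel, cov, records, truth
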