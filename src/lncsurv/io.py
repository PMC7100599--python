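"""Readers and writers for the pipeline's tab-separated formats.

All tables are plain TSV; floats serialise with 17 significant digits so
write -> read round-trips are exact.  BED intervals are 0-based half-open;
SEG files default to the same convention with a 1-based-inclusive import
dialect for files exported from tools that use it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .base import IExprMatrix
from .downstream import GeneInterval
from .regulon import MINetwork, Regulon, RegulonWeightProfiles

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_survival_tsv", "write_survival_tsv",
    "read_regulon_network_tsv", "write_regulon_network_tsv",
    "read_profiles_tsv", "write_profiles_tsv",
    "read_seg_tsv", "write_seg_tsv",
    "read_bed", "write_bed",
    "read_phenotype_tsv", "write_phenotype_tsv",
    "write_iexpr_tsv", "read_iexpr_tsv",
    "write_meta_results_tsv", "read_meta_results_tsv",
    "write_ground_truth", "read_ground_truth",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip",
                           **kw)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty or malformed file") from exc


# -- expression -------------------------------------------------------------

def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id",
                float_format=_FLOAT_FMT)


def read_expression_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        row = vals.isna().any(axis=1).to_numpy().argmax()
        raise ParseError(
            f"{path}: non-numeric cell in data line {row + 1}"
        )
    vals.index.name = None
    return vals.astype(float)


# -- survival ---------------------------------------------------------------

def write_survival_tsv(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_survival_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("sample", "time", "event", "dataset"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    bad = df.index[df["time"] <= 0]
    if len(bad):
        raise ParseError(f"{path}: non-positive time at row {bad[0] + 2}")
    if not df["event"].isin((0, 1)).all():
        bad = df.index[~df["event"].isin((0, 1))][0]
        raise ParseError(f"{path}: invalid event flag at row {bad + 2}")
    return df


# -- regulon network / profiles --------------------------------------------

def write_regulon_network_tsv(
    network: MINetwork, regulons: Mapping[str, Regulon], path
) -> None:
    rows = []
    for lnc, reg in regulons.items():
        for gene, (w, s) in sorted(reg.targets.items()):
            edge = (lnc, gene) if (lnc, gene) in network.edges else (gene, lnc)
            mi = network.edges.get(edge, np.nan)
            support = network.bootstrap_support.get(edge, 0)
            rows.append({"regulator": lnc, "target": gene, "mi": mi,
                         "weight": w, "sign": s,
                         "bootstrap_support": support})
    pd.DataFrame(
        rows, columns=["regulator", "target", "mi", "weight", "sign",
                       "bootstrap_support"]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_regulon_network_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = {"regulator", "target", "mi", "weight", "sign"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {need - set(df.columns)}")
    return df


def write_profiles_tsv(
    profiles: Iterable[RegulonWeightProfiles], path
) -> None:
    rows = []
    for prof in profiles:
        genes = sorted(set(prof.up) | set(prof.down))
        for g in genes:
            rows.append({
                "lncrna": prof.lncrna, "gene": g,
                "up_weight": prof.up.get(g, 0.0),
                "down_weight": prof.down.get(g, 0.0),
                "up_valid": int(prof.up_valid),
                "down_valid": int(prof.down_valid),
                "min_genes": prof.min_genes,
            })
    pd.DataFrame(
        rows, columns=["lncrna", "gene", "up_weight", "down_weight",
                       "up_valid", "down_valid", "min_genes"]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_profiles_tsv(path) -> list[RegulonWeightProfiles]:
    df = _read_tsv(path)
    out = []
    for lnc, sub in df.groupby("lncrna", sort=True):
        up = {r.gene: r.up_weight for r in sub.itertuples() if r.up_weight > 0}
        down = {r.gene: r.down_weight for r in sub.itertuples()
                if r.down_weight > 0}
        out.append(RegulonWeightProfiles(
            lncrna=str(lnc), up=up, down=down,
            up_valid=bool(sub["up_valid"].iloc[0]),
            down_valid=bool(sub["down_valid"].iloc[0]),
            min_genes=int(sub["min_genes"].iloc[0]),
        ))
    return out


# -- SEG / BED --------------------------------------------------------------

def write_seg_tsv(profiles: Mapping[str, pd.DataFrame], path) -> None:
    pd.concat(profiles.values(), ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_seg_tsv(path, dialect: str = "zero_half_open") -> dict[str, pd.DataFrame]:
    """Read a SEG-style table into per-patient frames.

    ``dialect`` is ``zero_half_open`` (native) or ``one_based_inclusive``
    (start shifted down by one on import).  Mixed-dialect files surface as
    coordinate violations (a 1-based file must have start >= 1).
    """
    df = _read_tsv(path)
    need = {"patient", "chrom", "start", "end", "signal", "call"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {need - set(df.columns)}")
    if dialect == "one_based_inclusive":
        if (df["start"] < 1).any():
            row = df.index[df["start"] < 1][0]
            raise ParseError(
                f"{path}: start < 1 at row {row + 2} under 1-based dialect "
                "(mixed-dialect file?)"
            )
        df = df.assign(start=df["start"] - 1)
    elif dialect != "zero_half_open":
        raise ValueError(f"unknown dialect {dialect!r}")
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
        raise ParseError(f"{path}: invalid coordinates at row {bad + 2}")
    if not df["call"].isin((-1, 0, 1)).all():
        bad = df.index[~df["call"].isin((-1, 0, 1))][0]
        raise ParseError(f"{path}: unknown call at row {bad + 2}")
    return {str(p): sub.reset_index(drop=True)
            for p, sub in df.groupby("patient", sort=True)}


def write_bed(intervals: pd.DataFrame, path) -> None:
    cols = intervals[["chrom", "start", "end", "gene", "strand"]].copy()
    cols.insert(4, "score", 0)
    cols.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if not 0 <= start < end:
                raise ParseError(f"{path}: line {ln}: invalid coordinates")
            gene = parts[3] if len(parts) > 3 else f"feature_{ln}"
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append({"gene": gene, "chrom": chrom, "start": start,
                         "end": end, "strand": strand})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "strand"])


# -- phenotype screen / iExpr / results -------------------------------------

def write_phenotype_tsv(screen: pd.DataFrame, path) -> None:
    screen.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = {"gene", "avg_phenotype_score", "p"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {need - set(df.columns)}")
    return df


def write_iexpr_tsv(result: IExprMatrix, path) -> None:
    rows = [
        {"lncrna": r.lncrna, "sample": r.sample, "pre_iexpr": r.pre_iexpr,
         "iexpr": r.iexpr, "n_perm": r.n_perm, "flags": ";".join(r.flags)}
        for r in result.records
    ]
    pd.DataFrame(
        rows, columns=["lncrna", "sample", "pre_iexpr", "iexpr", "n_perm",
                       "flags"]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_iexpr_tsv(path) -> pd.DataFrame:
    """Long iExpr table pivoted back to a lncRNA-by-sample matrix."""
    df = _read_tsv(path)
    return df.pivot(index="lncrna", columns="sample", values="iexpr")


def write_per_dataset_results_tsv(per_dataset: pd.DataFrame, path) -> None:
    """Per-dataset Cox fits: lncrna, dataset, beta, se, z, hr, p, n."""
    per_dataset.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_per_dataset_results_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = {"lncrna", "dataset", "z", "beta", "se", "p"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {need - set(df.columns)}")
    for col in ("beta", "se", "z", "hr", "p"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df


def write_km_curves_tsv(curves: Mapping[str, pd.DataFrame], path) -> None:
    """Kaplan-Meier step tables, one stacked TSV with a group column."""
    frames = [df.assign(group=label) for label, df in curves.items()]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_meta_results_tsv(meta_table: pd.DataFrame, path) -> None:
    meta_table.to_csv(path, sep="\t", index_label="lncrna",
                      float_format=_FLOAT_FMT)


def read_meta_results_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col=0)
    numeric = {"meta_z", "robust_meta_z", "meta_p", "fdr_bh", "bonferroni",
               "z", "beta", "se", "hr", "p"}
    for col in numeric & set(df.columns):
        df[col] = df[col].astype(float)
    return df


# -- ground truth manifest ---------------------------------------------------

def write_ground_truth(truth, path) -> None:
    payload = {
        "lncrnas": list(truth.activity.index),
        "samples": list(truth.activity.columns),
        "activity": truth.activity.to_numpy().tolist(),
        "regulons": {
            l: [[t, s, w] for t, s, w in entries]
            for l, entries in truth.regulons.items()
        },
        "prognostic_labels": truth.prognostic_labels,
        "betas": truth.betas,
        "essential_set": sorted(truth.essential_set),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path):
    from .simulate import GroundTruth

    payload = json.loads(Path(path).read_text())
    activity = pd.DataFrame(
        payload["activity"], index=payload["lncrnas"],
        columns=payload["samples"],
    )
    return GroundTruth(
        activity=activity,
        regulons={
            l: [(t, int(s), float(w)) for t, s, w in entries]
            for l, entries in payload["regulons"].items()
        },
        prognostic_labels=payload["prognostic_labels"],
        betas={k: float(v) for k, v in payload["betas"].items()},
        essential_set=set(payload["essential_set"]),
    )
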