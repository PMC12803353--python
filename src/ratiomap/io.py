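"""Plain-text table I/O and run-manifest helpers.

All tabular artifacts are TSV with a header row; trait matrices carry
their transformation stage in a JSON sidecar (``<file>.meta.json``).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .assoc import AssociationResult
from .datatypes import GenotypeMatrix, TraitMatrix
from .pgain import PGainRecord
from .preprocess import TestId


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_trait_matrix(tm: TraitMatrix, path) -> Path:
    path = Path(path)
    tm.data.to_csv(path, sep="\t", index_label="sample")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"stage": tm.stage}) + "\n")
    return path


def read_trait_matrix(path, stage: str | None = None) -> TraitMatrix:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", index_col="sample")
    if stage is None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        stage = json.loads(sidecar.read_text())["stage"] if sidecar.exists() else "raw"
    return TraitMatrix(data, stage)


def write_genotypes(geno: GenotypeMatrix, path) -> Path:
    path = Path(path)
    geno.data.to_csv(path, sep="\t", index_label="sample")
    return path


def read_genotypes(path) -> GenotypeMatrix:
    return GenotypeMatrix(pd.read_csv(path, sep="\t", index_col="sample"))


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "variant": r.variant,
                "kind": r.test.kind if r.test else "",
                "trait_a": r.test.trait_a if r.test else "",
                "trait_b": (r.test.trait_b or "") if r.test else "",
                "beta": r.beta,
                "se": r.se,
                "t_stat": r.t_stat,
                "neglog10_p": r.neglog10_p,
                "n": r.n,
                "df": r.df,
                "perfect_fit": r.perfect_fit,
            }
        )
    return pd.DataFrame(rows)


def frame_to_results(df: pd.DataFrame) -> list[AssociationResult]:
    out = []
    for _, row in df.iterrows():
        kind = row["kind"]
        test = None
        if kind == "single":
            test = TestId.single(str(row["trait_a"]))
        elif kind == "ratio":
            test = TestId.ratio(str(row["trait_a"]), str(row["trait_b"]))
        out.append(
            AssociationResult(
                variant=str(row["variant"]),
                test=test,
                beta=float(row["beta"]),
                se=float(row["se"]),
                t_stat=float(row["t_stat"]),
                neglog10_p=float(row["neglog10_p"]),
                n=int(row["n"]),
                df=int(row["df"]),
                perfect_fit=bool(row.get("perfect_fit", False)),
            )
        )
    return out


def pgains_to_frame(records: list[PGainRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant": [r.variant for r in records],
            "trait_a": [r.test.trait_a for r in records],
            "trait_b": [r.test.trait_b for r in records],
            "neglog10_p_a": [r.neglog10_p_a for r in records],
            "neglog10_p_b": [r.neglog10_p_b for r in records],
            "neglog10_p_ratio": [r.neglog10_p_ratio for r in records],
            "log10_pgain": [r.log10_pgain for r in records],
            "significant_ratio": [r.significant_ratio for r in records],
            "significant_pgain": [r.significant_pgain for r in records],
        }
    )
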