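"""Tab-delimited file formats and result writers.

Phenotype files carry one row per individual with required columns IID,
TRAIT, PRS, optional OFFSPRING and COHORT, covariates prefixed COV_ and
proxy fitness measures prefixed PROXY_.  Sibling-pair files carry PAIR_ID,
S1, S2.  Missing values are encoded NA; rows with missing required values
are dropped with a logged count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import PopoutResult
from .phenotypes import PhenotypeTable
from .sibs import SiblingPairTable, StandoutResult

__all__ = [
    "read_phenotype_table",
    "read_sibling_pairs",
    "write_popout_result",
    "write_standout_result",
    "write_snapshot",
    "read_snapshot",
    "write_manifest",
    "read_flat_config",
]

log = logging.getLogger("popout")

_FLOAT_FMT = "%.6g"


def _read_tsv(path: Union[str, Path], required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col}")
    return df


def read_phenotype_table(path: Union[str, Path]) -> PhenotypeTable:
    """Read a phenotype TSV into a :class:`PhenotypeTable`.

    Rows with missing TRAIT or PRS are excluded (count logged).  Non-numeric
    trait/PRS values raise with the offending row number.
    """
    df = _read_tsv(path, ["IID", "TRAIT", "PRS"])
    for col in ("TRAIT", "PRS"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based incl. header
            raise ValueError(f"non-numeric {col} value at line {row}")
        df[col] = coerced
    keep = df["TRAIT"].notna() & df["PRS"].notna()
    dropped = int((~keep).sum())
    if dropped:
        log.info("excluded %d rows with missing TRAIT/PRS", dropped)
    df = df[keep].reset_index(drop=True)
    cov_cols = [c for c in df.columns if c.startswith("COV_")]
    proxy_cols = [c for c in df.columns if c.startswith("PROXY_")]
    return PhenotypeTable(
        individual_id=df["IID"].to_numpy(),
        trait=df["TRAIT"].to_numpy(float),
        prs=df["PRS"].to_numpy(float),
        covariates=df[cov_cols].to_numpy(float) if cov_cols else None,
        offspring=df["OFFSPRING"].to_numpy() if "OFFSPRING" in df else None,
        cohort=df["COHORT"].to_numpy() if "COHORT" in df else None,
        proxies={c.removeprefix("PROXY_"): df[c].to_numpy(float) for c in proxy_cols},
    )


def read_sibling_pairs(path: Union[str, Path]) -> SiblingPairTable:
    """Read a sibling-pair TSV (PAIR_ID, S1, S2); duplicate PAIR_ID is an error."""
    df = _read_tsv(path, ["PAIR_ID", "S1", "S2"])
    if df["PAIR_ID"].duplicated().any():
        dup = df["PAIR_ID"][df["PAIR_ID"].duplicated()].iloc[0]
        raise ValueError(f"duplicate PAIR_ID {dup!r}")
    keep = df["S1"].notna() & df["S2"].notna()
    dropped = int((~keep).sum())
    if dropped:
        log.info("excluded %d pairs with missing sibling values", dropped)
    df = df[keep].reset_index(drop=True)
    return SiblingPairTable(
        pair_id=df["PAIR_ID"].to_numpy(),
        s1=df["S1"].to_numpy(float),
        s2=df["S2"].to_numpy(float),
    )


def write_popout_result(
    result: PopoutResult, prefix: Union[str, Path], q_values=None
) -> list[Path]:
    """Write a POPout result as <prefix>.popout.tsv (+ QC TSV if computed)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tail in enumerate(result.tails):
        rows.append(
            {
                "tail": tail.tail,
                "n": tail.n,
                "effect": tail.effect,
                "t": tail.t_statistic,
                "p": tail.p_value,
                "q": np.nan if q_values is None else q_values[i],
            }
        )
    out = prefix.with_suffix(".popout.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format=_FLOAT_FMT)
    written = [out]
    if result.qc_centile_p is not None:
        qc = pd.DataFrame(
            {"centile": np.arange(11, 91), "p": result.qc_centile_p}
        )
        out_qc = prefix.with_suffix(".qc.tsv")
        qc.to_csv(out_qc, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(out_qc)
    return written


def write_standout_result(result: StandoutResult, prefix: Union[str, Path]) -> Path:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "component": "mendelian",
            "tail": result.tail,
            "h2_hat": result.h2_hat,
            "z": result.mendelian.z,
            "p": result.mendelian.p,
            "n": result.mendelian.n,
            "r": result.mendelian.r,
            "pi0": result.mendelian.pi0,
        },
        {
            "component": "denovo",
            "tail": result.tail,
            "h2_hat": result.h2_hat,
            "z": result.denovo.z,
            "p": result.denovo.p,
            "n": result.denovo.n,
            "r": np.nan,
            "pi0": np.nan,
        },
        {
            "component": "combined",
            "tail": result.tail,
            "h2_hat": result.h2_hat,
            "z": result.chi2,
            "p": result.p,
            "n": result.mendelian.n,
            "r": np.nan,
            "pi0": np.nan,
        },
    ]
    out = prefix.with_suffix(".standout.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format=_FLOAT_FMT)
    return out


def write_snapshot(pop, prefix: Union[str, Path]) -> tuple[Path, Path]:
    """Serialize a simulation snapshot as two TSVs.

    <prefix>.mutations.tsv: one row per segregating mutation (id, position,
    effect, origin generation, carrier count).  <prefix>.carriage.tsv: one
    row per (haplotype, mutation) carriage.  The scalar baseline and
    generation go into the mutation file header comment-free via a leading
    row with id -1.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mut = pd.DataFrame(
        {
            "mutation_id": pop.mutation_id,
            "position": pop.positions,
            "effect": pop.effects,
            "origin_generation": pop.origin_generation,
            "count": pop.counts,
        }
    )
    meta = pd.DataFrame(
        {
            "mutation_id": [-1],
            "position": [pop.generation],
            "effect": [pop.baseline],
            "origin_generation": [0],
            "count": [0],
        }
    )
    mut_path = prefix.with_suffix(".mutations.tsv")
    pd.concat([meta, mut]).to_csv(mut_path, sep="\t", index=False, float_format="%.10g")
    hap_idx, mut_idx = np.nonzero(pop.genotypes)
    car = pd.DataFrame(
        {"haplotype": hap_idx, "mutation_id": pop.mutation_id[mut_idx]}
    )
    car_path = prefix.with_suffix(".carriage.tsv")
    car.to_csv(car_path, sep="\t", index=False)
    return mut_path, car_path


def read_snapshot(prefix: Union[str, Path]):
    """Rebuild a :class:`~popout.SimPopulation` from :func:`write_snapshot` files."""
    from .wf import SimPopulation

    prefix = Path(prefix)
    mut = pd.read_csv(prefix.with_suffix(".mutations.tsv"), sep="\t")
    meta = mut[mut["mutation_id"] == -1].iloc[0]
    mut = mut[mut["mutation_id"] != -1].reset_index(drop=True)
    car = pd.read_csv(prefix.with_suffix(".carriage.tsv"), sep="\t")
    n_hap = int(car["haplotype"].max()) + 1 if len(car) else 0
    id_to_col = {int(m): j for j, m in enumerate(mut["mutation_id"])}
    G = np.zeros((n_hap, len(mut)), dtype=bool)
    G[car["haplotype"], [id_to_col[int(m)] for m in car["mutation_id"]]] = True
    pop = SimPopulation(
        genotypes=G,
        positions=mut["position"].to_numpy(np.int64),
        effects=mut["effect"].to_numpy(float),
        origin_generation=mut["origin_generation"].to_numpy(np.int64),
        mutation_id=mut["mutation_id"].to_numpy(np.int64),
        baseline=float(meta["effect"]),
        traits=np.zeros(n_hap // 2),
        generation=int(meta["position"]),
    )
    pop.traits = pop.recompute_traits()
    return pop


def read_flat_config(path: Union[str, Path]) -> dict:
    """Parse a flat key-value config file (one `key = value` per line).

    Values are coerced to int, then float, then left as strings; blank
    lines and lines starting with # are ignored.
    """
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line {lineno}: {raw!r}")
        key, _, value = line.partition("=")
        value = value.strip()
        for cast in (int, float):
            try:
                out[key.strip()] = cast(value)
                break
            except ValueError:
                continue
        else:
            out[key.strip()] = value
    return out


def write_manifest(prefix: Union[str, Path], config: dict) -> Path:
    """Write a run manifest (config, seed, package version) next to results."""
    from . import __version__

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out = prefix.with_suffix(".manifest.json")
    payload = {"version": __version__, **config}
    out.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return out
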