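"""Bundled rotational-angle benchmark and its recomputation.

The package ships the published benchmark of 73 transmembrane helices from
14 α-helical membrane proteins (15 chains) with observed rotational angles,
moment-predicted angles, per-helix angular errors and per-chain MAAE.  The
check here recomputes every error, every per-chain MAAE, the global MAAE
and the error-distribution counts from the (observed, predicted) angle
pairs alone, and compares them with the printed values: printed angles are
rounded to 0.01°, so recomputed errors are allowed to differ from printed
errors by 0.01°.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from tmexpo.metrics import angular_error, error_percentile_summary, maae

PRINT_TOL = 0.01 + 1e-9  # printed values carry 2 decimals


@dataclass(frozen=True)
class BenchmarkRow:
    pdb_chain: str
    chain_maae: float
    helix: int
    sequence: str
    observed: float
    predicted: float
    error: float
    moment_length: float


def load_benchmark() -> list[BenchmarkRow]:
    rows: list[BenchmarkRow] = []
    path = resources.files("tmexpo.data").joinpath("helix_packing_benchmark.tsv")
    with path.open() as fh:
        content = (ln for ln in fh if not ln.startswith("#"))
        for rec in csv.DictReader(content, delimiter="\t"):
            rows.append(
                BenchmarkRow(
                    pdb_chain=rec["pdb_chain"],
                    chain_maae=float(rec["chain_maae"]),
                    helix=int(rec["helix"]),
                    sequence=rec["sequence"],
                    observed=float(rec["observed"]),
                    predicted=float(rec["predicted"]),
                    error=float(rec["error"]),
                    moment_length=float(rec["moment_length"]),
                )
            )
    if len(rows) != 73:
        raise ValueError(f"benchmark table corrupt: {len(rows)} rows, expected 73")
    return rows


def recompute() -> dict:
    """Recompute per-helix errors, per-chain and global MAAE, and the
    error-distribution counts from the bundled angle pairs."""
    rows = load_benchmark()
    pairs = [(r.observed, r.predicted) for r in rows]
    errors = [angular_error(x, y) for x, y in pairs]

    per_chain: dict[str, dict] = {}
    for r in rows:
        per_chain.setdefault(r.pdb_chain, {"pairs": [], "printed_maae": r.chain_maae})
        per_chain[r.pdb_chain]["pairs"].append((r.observed, r.predicted))
    for chain, d in per_chain.items():
        d["maae"] = maae(d["pairs"])
        del d["pairs"]

    summary = error_percentile_summary(
        pairs, thresholds=(("<", 10.0), ("<=", 43.0), (">=", 100.29)),
    )
    return {
        "n_helices": len(rows),
        "n_chains": len(per_chain),
        "errors": errors,
        "maae": maae(pairs),
        "per_chain": per_chain,
        "count_lt_10": summary[0]["count"],
        "count_le_43": summary[1]["count"],
        "percent_le_43": summary[1]["percent"],
        "count_ge_100_29": summary[2]["count"],
    }


def check() -> dict:
    """Compare every recomputed quantity with its printed counterpart.

    Returns a report with a boolean ``ok`` plus the largest deviations;
    used by the command-line ``benchmark-check``.
    """
    rows = load_benchmark()
    res = recompute()
    error_devs = [abs(e - r.error) for e, r in zip(res["errors"], rows)]
    chain_devs = {c: abs(d["maae"] - d["printed_maae"])
                  for c, d in res["per_chain"].items()}
    max_error_dev = max(error_devs)
    max_chain_dev = max(chain_devs.values())
    ok = bool(
        max_error_dev <= PRINT_TOL
        and max_chain_dev <= PRINT_TOL
        and res["count_lt_10"] == 13
        and res["count_ge_100_29"] == 6
        and round(res["percent_le_43"]) == 60
    )
    return {
        "ok": ok,
        "n_helices": res["n_helices"],
        "n_chains": res["n_chains"],
        "maae": res["maae"],
        "max_per_helix_error_deviation": max_error_dev,
        "max_per_chain_maae_deviation": max_chain_dev,
        "count_lt_10": res["count_lt_10"],
        "count_ge_100_29": res["count_ge_100_29"],
        "percent_le_43": res["percent_le_43"],
        "per_chain_maae": {c: d["maae"] for c, d in res["per_chain"].items()},
    }
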