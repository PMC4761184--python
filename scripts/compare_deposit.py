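#!/usr/bin/env python
"""Optional comparison against an externally downloaded compound deposit.

The original study's compound structures and endpoint values are archived
externally (LabArchives DOI 10.6070/H4VQ30PJ) and are not redistributed
here.  If you download them, this script recomputes Ub5/Ub6 for the
structures against a metabolite reference you supply, correlates each
endpoint with both scores, and -- when the deposit's own Ub values or
correlation table are provided -- prints them side by side.  Nothing in
the package's test suite depends on this script.

Usage:
  python scripts/compare_deposit.py \
      --compounds deposit.sdf --metabolites core.smi \
      --toxicity endpoints.csv [--reference-ub deposit_ub.csv] -o out.csv

``endpoints.csv`` needs columns: id, endpoint, log10_value.
``deposit_ub.csv`` (optional) needs: id, ub5, ub6.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

from unbio.combimol import MoleculeSet
from unbio.molgraph import read_sdf, read_smiles_lines
from unbio.toxcorr import CorrelationError, ToxicityRecord, correlate_endpoint
from unbio.unbiological import ub_table


def _read_structures(path: Path):
    text = path.read_text()
    if path.suffix in (".sdf", ".mol"):
        return read_sdf(text)
    return read_smiles_lines(text.splitlines())


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--compounds", type=Path, required=True)
    ap.add_argument("--metabolites", type=Path, required=True)
    ap.add_argument("--toxicity", type=Path, required=True)
    ap.add_argument("--reference-ub", type=Path, default=None)
    ap.add_argument("-o", "--out", type=Path, required=True)
    args = ap.parse_args()

    compounds = _read_structures(args.compounds)
    metabolites = MoleculeSet.from_smiles(
        [g.canonical for _, g in _read_structures(args.metabolites)]
    )
    table = ub_table(compounds, metabolites, ns=(5, 6))

    if args.reference_ub is not None:
        ref = pd.read_csv(args.reference_ub, dtype={"id": str})
        joined = table.merge(ref, on="id", suffixes=("", "_deposit"))
        for n in (5, 6):
            col, refcol = f"ub{n}", f"ub{n}_deposit"
            if refcol in joined:
                agree = (joined[col] == joined[refcol]).mean()
                print(f"Ub{n}: exact agreement with deposit on "
                      f"{agree:.1%} of {len(joined)} compounds")

    tox = pd.read_csv(args.toxicity, dtype={"id": str})
    rows = []
    for endpoint, group in tox.groupby("endpoint"):
        records = [
            ToxicityRecord(str(r.id), "", endpoint, float(r.log10_value))
            for r in group.itertuples()
        ]
        row = {"endpoint": endpoint, "n_records": len(records)}
        for n in (5, 6):
            try:
                res = correlate_endpoint(records, table, n, endpoint=endpoint)
                row[f"rho_ub{n}"], row[f"p_ub{n}"], row[f"tier_ub{n}"] = (
                    res.rho, res.p_value, res.tier
                )
            except CorrelationError as exc:
                row[f"tier_ub{n}"] = f"undefined: {exc}"
        rows.append(row)
    out = pd.DataFrame(rows)
    out.to_csv(args.out, index=False, float_format="%.6g")
    print(out.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
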