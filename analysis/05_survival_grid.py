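"""Univariate Cox survival scan over the 15-workflow grid.

Crosses five missing-data treatments (complete cases, random-forest,
kNN, max+1 and constant-35 imputation) with three normalizations (ENDO
= top-2 stable endogenous miRNAs, U6-snRNA, global mean) and Cox-scans
every miRNA for association with overall survival.  Writes all rows and
the P < 0.05 candidate table, and reports where the designed prognostic
target surfaced.
"""

import argparse
from pathlib import Path

from refstab import read_cp_table, run_workflow_grid
from refstab.io import read_sample_annotation

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 7) -> None:
    res = ROOT / "results"
    m = read_cp_table(
        res / "cp_masked.csv",
        role_map=res / "roles_clean.csv",
        plate_map=res / "plates_clean.csv",
    )
    ann = read_sample_annotation(res / "sim" / "annotation.csv")
    grid = run_workflow_grid(m, ann, seed=seed)

    grid.results.to_csv(res / "cox_all.csv", index=False)
    grid.hits.to_csv(res / "cox_hits.csv", index=False)

    print(f"workflows scanned: {len(grid.workflows)} (5 imputation arms x 3 schemes)")
    print(f"ENDO reference set (consensus top-2): {', '.join(grid.endo_ids)}")
    if grid.failures:
        print(f"failed grid cells: {grid.failures}")
    hits = grid.hits
    print(f"candidate OS predictors (P < {grid.alpha}): {len(hits)} rows, "
          f"{hits['target'].nunique()} distinct miRNAs")
    prog = hits[hits["target"] == "mir-prognostic"]
    cc = hits["workflow"].str.startswith("complete_cases")
    print(f"  designed prognostic miRNA significant in {len(prog)}/12 imputed "
          f"workflows (median HR {prog['hr'].median():.2f})"
          if len(prog)
          else "  designed prognostic miRNA not significant in any workflow")
    print(f"  hits in complete-case workflows: {int(cc.sum())} "
          "(the prognostic target cannot appear there: complete-case "
          "filtering drops targets with missing values)")
    print(f"wrote Cox tables to {res / 'cox_all.csv'} and {res / 'cox_hits.csv'}")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=7)
    main(**vars(p.parse_args()))
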