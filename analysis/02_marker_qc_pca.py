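#!/usr/bin/env python
"""QC the simulated marker data and summarize population structure.

Applies the MAF >= 5% / missingness <= 5% filters and r^2 >= 0.95 LD
pruning, then runs PCA on the retained genotypes. Writes the filter report
and the top principal components (the S0 population is expected to show
continuous variation rather than discrete clusters).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from breedarch import markers

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis_data"


def main(seed: int = 1) -> None:
    out = ROOT / "results"
    g = markers.read_genotypes(DATA / "genotypes.tsv")
    groups = pd.read_csv(DATA / "pedigree.csv").set_index("id")["group"]
    g.groups = groups.reindex([str(i) for i in g.ids]).to_numpy()

    g_f, report = markers.filter_markers(g)
    g_p = markers.ld_prune(g_f)
    markers.write_tsv(g_p, DATA / "genotypes_qc.tsv")
    (out / "table_filter_report.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n"
    )
    scores, ve = markers.pca_markers(g_p, n_components=5)
    pca = pd.DataFrame(scores, columns=[f"PC{k+1}" for k in range(5)])
    pca.insert(0, "id", g_p.ids)
    pca.insert(1, "group", g_p.groups)
    pca.to_csv(out / "table_pca.csv", index=False, float_format="%.5g")

    print(f"markers: {report.n_input} -> {report.n_retained} after QC "
          f"-> {g_p.n_markers} after LD pruning")
    print("variance explained by PC1-5:", [round(float(v), 3) for v in ve])


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
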