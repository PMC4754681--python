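#!/usr/bin/env python
"""In-silico specificity test: run every designed pair against every library
species and report the pair x species amplification matrix (the in-silico
analog of a multi-lane gel: a specific pair shows a single on-target band).
"""

import pandas as pd
from pathlib import Path

from psocid_id import PCRPair, read_fasta, specificity_matrix

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_pairs(path):
    table = pd.read_csv(path, sep="\t", dtype=str)
    pairs = []
    for sp, grp in table.groupby("species", sort=False):
        f = grp[grp["role"] == "F"].iloc[0]
        r = grp[grp["role"] == "R"].iloc[0]
        pairs.append(PCRPair(sp, f["seq_5to3"], r["seq_5to3"],
                             int(f["target_fragment"])))
    return pairs


def main() -> None:
    lib = read_fasta(RESULTS / "simulated" / "library.fasta",
                     RESULTS / "simulated" / "library.meta.tsv")
    pairs = load_pairs(RESULTS / "designed_pairs.tsv")
    mat = specificity_matrix(pairs, lib)
    mat.write_tsv(RESULTS / "specificity_matrix.tsv")

    print(mat.amplified.astype(int).to_string())
    print(f"\n{mat.n_specific}/{len(mat.pair_species)} pairs amplify their "
          f"own species and nothing else"
          + (" (diagonal matrix)" if mat.is_diagonal else ""))


if __name__ == "__main__":
    main()
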