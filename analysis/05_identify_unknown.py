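#!/usr/bin/env python
"""Blinded identification of spiked field samples.

Draws one 'unknown' per species from the simulation (1% sequence noise,
labels stripped), runs the species-specific panel against each, and reports
the call plus the best-match similarity to the barcode library — the
in-silico analog of identifying an intercepted psocid.
"""

import argparse
from pathlib import Path

from psocid_id import SimulationConfig, identify, read_fasta, simulate_library, spike_unknown

import importlib.util

RESULTS = Path(__file__).resolve().parent.parent / "results"
_spec = importlib.util.spec_from_file_location(
    "spec04", Path(__file__).with_name("04_specificity_matrix.py"))
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_pairs = _mod.load_pairs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1,
                    help="must match the seed used in 01_simulate_library")
    ap.add_argument("--noise", type=float, default=0.01)
    args = ap.parse_args()

    sim = simulate_library(SimulationConfig(seed=args.seed))
    lib = read_fasta(RESULTS / "simulated" / "library.fasta",
                     RESULTS / "simulated" / "library.meta.tsv")
    pairs = load_pairs(RESULTS / "designed_pairs.tsv")

    correct = 0
    for i, sp in enumerate(lib.species):
        unknown = spike_unknown(sim, sp, noise_rate=args.noise,
                                seed=args.seed + 1009 + i)
        call = identify(unknown, pairs, lib)
        ok = call.called_species == sp
        correct += ok
        print(f"true={sp:20s} called={call.called_species:20s} "
              f"best match {call.best_match_id} "
              f"({call.best_match_similarity:.2f}% identity) "
              f"{'OK' if ok else 'MISS'}")
    print(f"\n{correct}/{len(lib.species)} unknowns identified correctly "
          f"at {100 * args.noise:.0f}% noise")


if __name__ == "__main__":
    main()
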