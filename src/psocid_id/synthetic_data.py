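"""Seeded generator of ITS2-like barcode libraries.

The generator emulates the statistical structure the identification pipeline
relies on: a star phylogeny of 10 deeply diverged species (each species root
drawn by mutating a shared ancestral core), a species-level core length in
the 293-614 bp range, identical conserved flanks on every record (the
universal-primer sites of the rDNA coding regions around ITS2), and shallow
within-species variation (substitutions plus rare short indels).  Deep
divergence with within-species conservation yields species-private fixed
differences — the diagnostic SNPs — and a wide barcoding gap.

Substitutions are uniform across the three alternative bases (Jukes-Cantor
style); no transition bias is simulated, so realized transition and
transversion proportions are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .seq_io import BarcodeLibrary, SequenceRecord, write_fasta, write_metadata

#: The ten study species, ordered as in the population survey.
SPECIES_NAMES = [
    "L. entomophila", "L. bostrychophila", "L. decolor", "L. paeta",
    "L. corrodens", "L. brunnea", "L. mendax", "L. pearmani",
    "L. tricolor", "L. rufa",
]

#: Populations per species in the survey (totals 35).
DEFAULT_POPS = (4, 9, 4, 8, 4, 2, 1, 1, 1, 1)

COUNTRIES = ["China", "Czech Republic", "Denmark", "Germany", "USA"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    n_species: int = 10
    pops_per_species: tuple[int, ...] | int = DEFAULT_POPS
    seqs_per_pop: int = 6
    core_len_range: tuple[int, int] = (293, 614)
    flank_len: int = 60
    inter_div: float = 0.25    # substitutions/site, ancestor -> species root
    intra_rate: float = 0.005  # substitutions/site, root -> individual
    indel_rate: float = 0.002  # indel events/site per individual
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if not (0 <= self.intra_rate < 1 and 0 <= self.inter_div < 1
                and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.inter_div <= self.intra_rate:
            raise ValueError("inter_div must exceed intra_rate")
        if self.core_len_range[0] < 1 or self.flank_len < 0:
            raise ValueError("lengths must be positive")
        if isinstance(self.pops_per_species, int):
            self.pops_per_species = (self.pops_per_species,) * self.n_species
        else:
            self.pops_per_species = tuple(self.pops_per_species)
        if len(self.pops_per_species) != self.n_species:
            raise ValueError("pops_per_species length must equal n_species")


@dataclass
class SimulatedLibrary:
    library: BarcodeLibrary
    truth: dict[str, str]            # record id -> species of origin
    provenance: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _apply_indels(rng: np.random.Generator, seq: np.ndarray,
                  rate: float) -> np.ndarray:
    if rate == 0.0:
        return seq
    events = np.nonzero(rng.random(len(seq)) < rate)[0]
    if events.size == 0:
        return seq
    pieces = []
    prev = 0
    for pos in events:
        if pos < prev:
            continue
        pieces.append(seq[prev:pos])
        length = int(rng.geometric(0.5))  # mean 2
        if rng.random() < 0.5:
            pieces.append(_random_seq(rng, length))   # insertion
            prev = pos
        else:
            prev = pos + length                        # deletion
    pieces.append(seq[prev:])
    return np.concatenate(pieces) if pieces else seq


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_library(cfg: SimulationConfig) -> SimulatedLibrary:
    """Generate a labelled library under a star phylogeny; fully seeded."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.core_len_range
    ancestor = _random_seq(rng, hi)
    left = _to_str(_random_seq(rng, cfg.flank_len))
    right = _to_str(_random_seq(rng, cfg.flank_len))

    names = [SPECIES_NAMES[i] if i < len(SPECIES_NAMES) else f"sp{i + 1:02d}"
             for i in range(cfg.n_species)]
    records = []
    truth = {}
    pop_counter = 0
    for s, (name, n_pops) in enumerate(zip(names, cfg.pops_per_species)):
        root = _mutate(rng, ancestor, cfg.inter_div)
        core_len = int(rng.integers(lo, hi + 1))
        root = root[:core_len]
        slug = name.split()[-1][:4]
        for p in range(n_pops):
            country = COUNTRIES[pop_counter % len(COUNTRIES)]
            pop_code = f"{slug}-p{p + 1:02d}-{country.replace(' ', '')}"
            pop_counter += 1
            for k in range(cfg.seqs_per_pop):
                core = _mutate(rng, root, cfg.intra_rate)
                core = _apply_indels(rng, core, cfg.indel_rate)
                rec = SequenceRecord(
                    id=f"{slug}_{p + 1:02d}_{k + 1:02d}",
                    seq=left + _to_str(core) + right,
                    species=name, population=pop_code, country=country,
                )
                records.append(rec)
                truth[rec.id] = name
    prov = asdict(cfg)
    return SimulatedLibrary(BarcodeLibrary(records), truth, prov)


def spike_unknown(sim: SimulatedLibrary, species: str, noise_rate: float,
                  seed: int) -> SequenceRecord:
    """One record of `species` mutated at `noise_rate`, relabelled unknown —
    an in-silico field sample for testing identification."""
    members = sim.library.records_of(species)
    if not members:
        raise ValueError(f"unknown species {species!r}")
    rng = np.random.default_rng(seed)
    src = members[int(rng.integers(0, len(members)))]
    codes = np.frombuffer(src.seq.encode(), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for i, ch in enumerate("ACGT"):
        lut[ord(ch)] = i
    mutated = _mutate(rng, lut[codes], noise_rate)
    return SequenceRecord(id="unknown", seq=_to_str(mutated), species="unknown")


def write_simulated(sim: SimulatedLibrary, outdir: str | Path,
                    stem: str = "library") -> None:
    """Write FASTA + metadata TSV + truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.library, outdir / f"{stem}.fasta")
    write_metadata(sim.library, outdir / f"{stem}.meta.tsv")
    with open(outdir / f"{stem}.truth.tsv", "w") as fh:
        fh.write("id\tspecies\n")
        for rid, sp in sim.truth.items():
            fh.write(f"{rid}\t{sp}\n")
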