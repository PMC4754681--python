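"""Species-specific primer design against diagnostic SNP sites.

Candidates are windows of the target species' consensus whose 3'-terminal
bases sit on a diagnostic SNP (allele-specific PCR logic: a 3' mismatch on
every non-target template blocks extension).  Each candidate is screened
with the published panel's four criteria:

* GC content between 30 and 70 %;
* |ΔG| of the 3'-terminal pentamer at most 9 kcal/mol (overly stable 3'
  ends promote mispriming);
* no hairpin stem longer than 3 contiguous base pairs, and no 3'-anchored
  (extensible) self- or cross-dimer stem longer than 3;
* a 0-100 false-priming (error initiation) score at most 100 against the
  whole-library consensus.

Melting temperatures and free energies come from unified nearest-neighbor
thermodynamics (SantaLucia's parameter set) with an entropic salt
correction; Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15 for
non-self-complementary oligos at total strand concentration C_T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._align_core import encode
from .msa_snp import DiagnosticSite, MultipleAlignment, find_diagnostic_sites
from .seq_io import BarcodeLibrary, reverse_complement

R_GAS = 1.987  # cal / (mol K)

# Unified nearest-neighbor parameters: ΔH in kcal/mol, ΔS in cal/(mol K),
# one entry per Watson-Crick dinucleotide stack (5'->3' top strand).
NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
# Duplex initiation per terminal base.
INIT_DH = {"A": 2.3, "T": 2.3, "C": 0.1, "G": 0.1}
INIT_DS = {"A": 4.1, "T": 4.1, "C": -2.8, "G": -2.8}
SYM_DS = -1.4  # self-complementary symmetry correction

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ThermoModel:
    """Nearest-neighbor tables plus solution conditions."""

    nn_dh: dict = field(default_factory=lambda: dict(NN_DH))
    nn_ds: dict = field(default_factory=lambda: dict(NN_DS))
    init_dh: dict = field(default_factory=lambda: dict(INIT_DH))
    init_ds: dict = field(default_factory=lambda: dict(INIT_DS))
    na_conc: float = 0.05        # monovalent cations, mol/L
    oligo_conc: float = 250e-9   # total strand concentration, mol/L

    def __post_init__(self) -> None:
        if self.na_conc <= 0 or self.oligo_conc <= 0:
            raise ValueError("concentrations must be positive")
        missing = {s for s in NN_DH if s not in self.nn_dh or s not in self.nn_ds}
        if missing:
            raise ValueError(f"missing nearest-neighbor stacks: {sorted(missing)}")


DEFAULT_THERMO = ThermoModel()


def _check_unambiguous(seq: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in "ACGT":
            raise ValueError(f"ambiguous/invalid base {ch!r} at position {pos}")
    return seq


def gc_content(seq: str) -> float:
    """GC percentage of an unambiguous DNA string."""
    seq = _check_unambiguous(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def duplex_dh_ds(seq: str, model: ThermoModel = DEFAULT_THERMO) -> tuple[float, float]:
    """Total nearest-neighbor ΔH (kcal/mol) and ΔS (cal/mol·K), no salt."""
    seq = _check_unambiguous(seq)
    dh = model.init_dh[seq[0]] + model.init_dh[seq[-1]]
    ds = model.init_ds[seq[0]] + model.init_ds[seq[-1]]
    for i in range(len(seq) - 1):
        stack = seq[i:i + 2]
        dh += model.nn_dh[stack]
        ds += model.nn_ds[stack]
    return dh, ds


def melting_temp(seq: str, model: ThermoModel = DEFAULT_THERMO) -> float:
    """Nearest-neighbor Tm in °C with entropic salt correction."""
    seq = _check_unambiguous(seq)
    if len(seq) < 8:
        raise ValueError("Tm model requires length >= 8")
    dh, ds = duplex_dh_ds(seq, model)
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        ds += SYM_DS
        ct = model.oligo_conc
    else:
        ct = model.oligo_conc / 4.0
    ds += 0.368 * (len(seq) - 1) * math.log(model.na_conc)
    return dh * 1000.0 / (ds + R_GAS * math.log(ct)) - 273.15


def dg37_stack(stack: str, model: ThermoModel = DEFAULT_THERMO) -> float:
    """ΔG at 37 °C (kcal/mol) for one dinucleotide stack."""
    return model.nn_dh[stack] - 310.15 * model.nn_ds[stack] / 1000.0


def dg_3prime(seq: str, model: ThermoModel = DEFAULT_THERMO) -> float:
    """Stacking ΔG37 of the 3'-terminal pentamer (four stacks); negative for
    stable ends."""
    seq = _check_unambiguous(seq)
    if len(seq) < 6:
        raise ValueError("3' ΔG requires length >= 6")
    pent = seq[-5:]
    return sum(dg37_stack(pent[i:i + 2], model) for i in range(4))


def max_complementary_stem(a: str, b: str) -> int:
    """Longest contiguous antiparallel Watson-Crick duplex between a and b
    over all offsets (self-dimer when a == b)."""
    if not a or not b:
        raise ValueError("empty sequence")
    a = _check_unambiguous(a)
    rb = _check_unambiguous(b)[::-1]
    best = 0
    la, lb = len(a), len(rb)
    for off in range(-(la - 1), lb):
        run = 0
        for i in range(la):
            k = i + off
            if 0 <= k < lb and _PAIR[a[i]] == rb[k]:
                run += 1
                if run > best:
                    best = run
            else:
                run = 0
    return best


def _anchored_3p_stem(a: str, b: str) -> int:
    """Longest contiguous duplex anchored at a's 3'-terminal base against b."""
    best = 0
    la = len(a)
    for j in range(len(b)):
        run = 0
        i = la - 1
        k = j
        while i >= 0 and k < len(b) and _PAIR[a[i]] == b[k]:
            run += 1
            i -= 1
            k += 1
        if run > best:
            best = run
    return best


def three_prime_dimer_stem(a: str, b: str) -> int:
    """Longest contiguous duplex involving either oligo's 3'-terminal base.

    This is the extensible-dimer statistic the design filters use: a duplex
    buried in the middle of an oligo cannot prime, so only 3'-anchored stems
    are screened.  (The published primer panel is consistent with this
    reading and grossly violates an any-offset stem cap.)
    """
    a = _check_unambiguous(a)
    b = _check_unambiguous(b)
    return max(_anchored_3p_stem(a, b), _anchored_3p_stem(b, a))


def max_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest contiguous self-paired stem folding the oligo back on itself
    with a loop of at least `min_loop` unpaired bases."""
    seq = _check_unambiguous(seq)
    n = len(seq)
    best = 0
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            run = 0
            x, y = i, j
            while x < y and _PAIR[seq[x]] == seq[y] and (y - x - 1) >= min_loop:
                run += 1
                x += 1
                y -= 1
            if run > best:
                best = run
    return best


def false_priming_score(primer: str, template: str,
                        exclude: tuple[int, int] | None = None,
                        both_strands: bool = True) -> float:
    """Maximum 3'-weighted identity (0-100) of the primer against template
    windows, excluding the intended site.

    Positions are weighted 2 for the 3'-most five bases and 1 elsewhere.
    `exclude` is a 1-based inclusive template interval (the intended
    footprint); windows overlapping it are skipped on both strands.
    """
    primer = _check_unambiguous(primer)
    L = len(primer)
    if len(template) < L:
        raise ValueError("template shorter than primer")
    w = np.ones(L)
    w[-5:] = 2.0
    wsum = w.sum()
    p = encode(primer)

    def scan(t_seq: str, minus: bool) -> float:
        t = encode(t_seq)
        wins = np.lib.stride_tricks.sliding_window_view(t, L)
        matches = (wins == p).astype(float)
        scores = 100.0 * (matches @ w) / wsum
        if exclude is not None:
            s0, e0 = exclude
            n = len(t_seq)
            for start in range(wins.shape[0]):
                if minus:
                    # window [start, start+L-1] on revcomp == template
                    # [n-start-L+1, n-start] in 1-based plus coordinates
                    ws, we = n - start - L + 1, n - start
                else:
                    ws, we = start + 1, start + L
                if ws <= e0 and we >= s0:
                    scores[start] = -1.0
        return float(scores.max()) if scores.size else 0.0

    best = scan(template, minus=False)
    if both_strands:
        best = max(best, scan(reverse_complement(template), minus=True))
    return max(best, 0.0)


# ---------------------------------------------------------------------------
# Consensus extraction from the MSA
# ---------------------------------------------------------------------------

def species_consensus(msa: MultipleAlignment, lib: BarcodeLibrary,
                      species: str) -> tuple[str, list[int]]:
    """Majority-rule species consensus with per-position MSA columns (1-based).

    Columns where gaps are in the majority are dropped (no physical base in
    most individuals); ties between bases, or an ambiguity-code majority,
    become 'N' and are excluded from candidate windows.  Minority variants
    are tolerated here — fixation is enforced separately at diagnostic
    anchor columns, and the in-silico PCR allows non-3' mismatches.
    """
    ids = set(lib.species_index[species])
    rows = [row for rid, row in zip(msa.ids, msa.rows) if rid in ids]
    cons = []
    cols = []
    for col in range(msa.column_count):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[col]
            counts[ch] = counts.get(ch, 0) + 1
        n_gap = counts.pop("-", 0)
        if n_gap >= len(rows) - n_gap:       # gap majority: no consensus base
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if ranked[0][0] not in "ACGT" or (
                len(ranked) > 1 and ranked[1][1] == ranked[0][1]):
            cons.append("N")
        else:
            cons.append(ranked[0][0])
        cols.append(col + 1)
    return "".join(cons), cols


def library_consensus(msa: MultipleAlignment) -> tuple[str, list[int]]:
    """Majority-rule consensus over all rows; returns (sequence, per-column
    1-based consensus position or 0 where the column is majority-gap)."""
    cons = []
    col_to_pos = []
    for col in range(msa.column_count):
        counts: dict[str, int] = {}
        for r in msa.rows:
            counts[r[col]] = counts.get(r[col], 0) + 1
        ch = min(counts, key=lambda c: (-counts[c], c))  # ties -> alphabetical
        if ch in "ACGT":
            cons.append(ch)
            col_to_pos.append(len(cons))
        else:
            col_to_pos.append(0)
    return "".join(cons), col_to_pos


# ---------------------------------------------------------------------------
# Candidate enumeration and pair selection
# ---------------------------------------------------------------------------

@dataclass
class DesignConfig:
    """Tunable design constraints; defaults follow the published criteria."""

    primer_len: tuple[int, int] = (18, 25)
    tm_range: tuple[float, float] = (50.0, 65.0)
    gc_range: tuple[float, float] = (30.0, 70.0)
    dg3_abs_max: float = 9.0
    max_stem: int = 3
    max_false_priming: float = 100.0
    product_range: tuple[int, int] = (100, 300)
    anchor_window: int = 3  # 3'-terminal positions that must cover a SNP
    thermo: ThermoModel = field(default_factory=ThermoModel)
    # Wet-lab annealing temperatures, carried as documentation only.
    universal_annealing_c: float = 52.0
    specific_annealing_c: float = 53.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thermo = ThermoModel(**raw.pop("thermo", {}))
        for key in ("primer_len", "tm_range", "gc_range", "product_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(thermo=thermo, **raw)


@dataclass(frozen=True)
class PrimerCandidate:
    seq: str
    strand: str                     # "forward" | "reverse"
    msa_start: int                  # 1-based MSA column of the 5' end
    cons_five_prime: int            # 1-based species-consensus position of 5' end
    tm: float
    gc_pct: float
    dg3: float
    max_self_stem: int      # longest contiguous self-duplex, any offset (reported)
    self_dimer_3p: int      # longest 3'-anchored self-duplex (filtered)
    max_hairpin_stem: int
    false_priming: float
    diagnostic_positions: tuple[int, ...]  # from the 3' end, 1 = terminus

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class EnumerationResult:
    candidates: list[PrimerCandidate]
    tally: dict[str, int]


def enumerate_candidates(msa: MultipleAlignment, lib: BarcodeLibrary,
                         sites: Sequence[DiagnosticSite], species: str,
                         config: DesignConfig | None = None) -> EnumerationResult:
    """All primer windows on the species consensus anchored (3'-terminal
    `anchor_window` bases) on a diagnostic SNP and passing every filter."""
    cfg = config or DesignConfig()
    cons, cols = species_consensus(msa, lib, species)
    diag_cols = {s.column for s in sites}
    diag = [c in diag_cols for c in cols]
    lib_cons, col_to_pos = library_consensus(msa)

    tally = {k: 0 for k in ("no_anchor", "ambiguous_base", "gc", "tm", "dg3",
                            "self_dimer", "hairpin", "false_priming", "passed")}
    out: list[PrimerCandidate] = []
    lmin, lmax = cfg.primer_len
    for L in range(lmin, lmax + 1):
        for start in range(0, len(cons) - L + 1):
            window = cons[start:start + L]
            for strand in ("forward", "reverse"):
                if strand == "forward":
                    anchor_idx = range(start + L - cfg.anchor_window, start + L)
                else:
                    anchor_idx = range(start, start + cfg.anchor_window)
                if not any(diag[i] for i in anchor_idx):
                    tally["no_anchor"] += 1
                    continue
                if "N" in window:
                    tally["ambiguous_base"] += 1
                    continue
                if strand == "forward":
                    seq = window
                    five = start + 1
                    msa_start = cols[start]
                    diag_pos = tuple(L - (i - start) for i in range(start, start + L)
                                     if diag[i])
                else:
                    seq = reverse_complement(window)
                    five = start + L
                    msa_start = cols[start + L - 1]
                    diag_pos = tuple((i - start) + 1 for i in range(start, start + L)
                                     if diag[i])

                gc = gc_content(seq)
                ok = True
                if not (cfg.gc_range[0] <= gc <= cfg.gc_range[1]):
                    tally["gc"] += 1
                    ok = False
                tm = melting_temp(seq, cfg.thermo)
                if not (cfg.tm_range[0] <= tm <= cfg.tm_range[1]):
                    tally["tm"] += 1
                    ok = False
                dg3 = dg_3prime(seq, cfg.thermo)
                if abs(dg3) > cfg.dg3_abs_max:
                    tally["dg3"] += 1
                    ok = False
                if not ok:
                    continue
                self_stem = max_complementary_stem(seq, seq)
                dimer_3p = three_prime_dimer_stem(seq, seq)
                if dimer_3p > cfg.max_stem:
                    tally["self_dimer"] += 1
                    continue
                hairpin = max_hairpin_stem(seq)
                if hairpin > cfg.max_stem:
                    tally["hairpin"] += 1
                    continue
                footprint = [col_to_pos[c - 1] for c in cols[start:start + L]
                             if col_to_pos[c - 1] > 0]
                exclude = (min(footprint), max(footprint)) if footprint else None
                fp = false_priming_score(seq, lib_cons, exclude=exclude)
                if fp > cfg.max_false_priming:
                    tally["false_priming"] += 1
                    continue
                tally["passed"] += 1
                out.append(PrimerCandidate(seq, strand, msa_start, five, tm, gc,
                                           dg3, self_stem, dimer_3p, hairpin, fp,
                                           tuple(sorted(diag_pos))))
    return EnumerationResult(out, tally)


@dataclass
class PrimerPair:
    species: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_len: int        # 5' of forward to 5' of reverse, inclusive
    pair_dimer_stem: int    # longest 3'-anchored cross-duplex (qualification)
    tm_diff: float

    @property
    def name(self) -> str:
        return f"{self.species}:{self.forward.cons_five_prime}F/" \
               f"{self.reverse.cons_five_prime}R"


def select_optimal_pair(cands: Sequence[PrimerCandidate],
                        product_range: tuple[int, int] = (100, 300),
                        max_pair_stem: int = 3,
                        species: str = "") -> PrimerPair:
    """Best forward/reverse combination by lexicographic cost.

    Pairs with a cross-dimer stem over `max_pair_stem` are disqualified;
    the rest are ranked by |ΔTm|, then combined false priming, then product
    length, then leftmost forward position.
    """
    fwd = [c for c in cands if c.strand == "forward"]
    rev = [c for c in cands if c.strand == "reverse"]
    feasible = []
    for f in fwd:
        for r in rev:
            pl = r.cons_five_prime - f.cons_five_prime + 1
            if pl < len(f) + len(r):
                continue
            if not (product_range[0] <= pl <= product_range[1]):
                continue
            feasible.append((abs(f.tm - r.tm), f.false_priming + r.false_priming,
                             pl, f.cons_five_prime, f, r))
    if not feasible:
        raise ValueError("no feasible primer pair in the product range")
    feasible.sort(key=lambda x: x[:4])
    for tm_diff, _, pl, _, f, r in feasible:
        stem = three_prime_dimer_stem(f.seq, r.seq)
        if stem <= max_pair_stem:
            return PrimerPair(species, f, r, pl, stem, tm_diff)
    raise ValueError("all feasible pairs disqualified by cross-dimer stems")


@dataclass
class DesignResult:
    species: str
    pair: PrimerPair | None
    n_sites: int
    tally: dict[str, int]
    error: str = ""


def design_for_species(msa: MultipleAlignment, lib: BarcodeLibrary, species: str,
                       config: DesignConfig | None = None) -> DesignResult:
    """Full single-species design: diagnostic sites -> candidates -> best pair."""
    cfg = config or DesignConfig()
    sites = find_diagnostic_sites(msa, lib, species)
    if not sites:
        return DesignResult(species, None, 0, {}, "no diagnostic site")
    enum = enumerate_candidates(msa, lib, sites, species, cfg)
    if not enum.candidates:
        return DesignResult(species, None, len(sites), enum.tally,
                            "no candidate passed all filters")
    try:
        pair = select_optimal_pair(enum.candidates, cfg.product_range,
                                   cfg.max_stem, species=species)
    except ValueError as exc:
        return DesignResult(species, None, len(sites), enum.tally, str(exc))
    return DesignResult(species, pair, len(sites), enum.tally)


def design_all(msa: MultipleAlignment, lib: BarcodeLibrary,
               config: DesignConfig | None = None) -> dict[str, DesignResult]:
    return {sp: design_for_species(msa, lib, sp, config) for sp in lib.species}


def write_pairs_tsv(pairs: Sequence[PrimerPair], path: str | Path) -> None:
    """Primer-pair report mirroring the published panel's columns."""
    import pandas as pd
    rows = []
    for p in pairs:
        for role, cand in (("F", p.forward), ("R", p.reverse)):
            rows.append({
                "species": p.species,
                "primer_name": f"{cand.cons_five_prime}{role}",
                "role": role,
                "seq_5to3": cand.seq,
                "length": len(cand),
                "tm_c": round(cand.tm, 1),
                "gc_pct": round(cand.gc_pct, 1),
                "target_fragment": p.product_len,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
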