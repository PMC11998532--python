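"""Synthetic hairpin populations and genome-like backbones.

Two generators back every downstream analysis:

* :func:`random_hairpin` / :func:`generate_catalog` build populations of
  random stem-loops — a 5' arm of uniform random nucleotides, a short apical
  loop, and a 3' arm whose positions are Watson-Crick complementary to their
  mirrored 5' partner with a given probability ("complementarity").  The
  default grid (stems 10/15/30/45/60/75/90 nt, 5-nt loop, complementarity
  0-100% in 10% steps) spans hairpins from fully paired to fully random.
* :func:`synth_backbone` builds a genome-like context: strongly paired
  low-entropy hairpins joined by unpaired pyrimidine linkers, together with
  the intended reference structure — a stand-in for a real viral 3' UTR when
  testing insertion sites.

All randomness flows from one root seed; each catalog cell draws from its
own deterministically derived stream, so results are independent of
iteration order and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .sequences import RnaSequence, WC_COMPLEMENT
from .structure import HairpinRecord, SecondaryStructure, characterize_hairpin

BASES = "ACGU"

DEFAULT_STEM_LENGTHS = (10, 15, 30, 45, 60, 75, 90)
DEFAULT_COMPLEMENTARITIES = tuple(range(0, 101, 10))
DEFAULT_LOOP_LEN = 5


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-hairpin population.

    ``replicates`` is the number of hairpins drawn per
    (stem length, complementarity) cell; ``exact_count`` switches the
    complementarity semantics from per-position Bernoulli forcing to an
    exact floor(c/100 * stem_len) forced positions chosen uniformly.
    """

    stem_lengths: tuple[int, ...] = DEFAULT_STEM_LENGTHS
    loop_len: int = DEFAULT_LOOP_LEN
    complementarities: tuple[int, ...] = DEFAULT_COMPLEMENTARITIES
    replicates: int = 1
    seed: int = 0
    exact_count: bool = False

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.stem_lengths):
            raise ValueError("stem lengths must be >= 1")
        if any(not (0 <= c <= 100) for c in self.complementarities):
            raise ValueError("complementarities must lie in [0, 100]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_records(self) -> int:
        return len(self.stem_lengths) * len(self.complementarities) * self.replicates


@dataclass
class HairpinCatalog:
    """A generated, folded and characterized hairpin population."""

    spec: GeneratorSpec
    records: list[HairpinRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self):
        """Tabular view: one row per hairpin with generator metadata."""
        import pandas as pd

        rows = []
        for r in self.records:
            m = r.metadata or {}
            rows.append(
                {
                    "id": r.sequence.id,
                    "stem_len": m.get("stem_len"),
                    "complementarity": m.get("complementarity"),
                    "replicate": m.get("replicate"),
                    "length": r.length,
                    "delta_g": r.delta_g,
                    "ape": round(r.ape, 4),
                    "apical_loops": r.apical_loops,
                    "simple_hairpin": r.simple_hairpin,
                    "sequence": r.sequence.residues,
                }
            )
        return pd.DataFrame(rows)


def _random_arm(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[k] for k in rng.integers(0, 4, size=length))


def random_hairpin(
    stem_len: int,
    loop_len: int,
    complementarity: float,
    rng: np.random.Generator,
    *,
    exact_count: bool = False,
    seq_id: str = "random_hairpin",
) -> RnaSequence:
    """Draw one random stem-loop sequence.

    The 5' arm and loop are uniform random ACGU.  Each 3'-arm position
    mirrors 5' position i (3'-arm position stem_len - i + 1 pairs with arm
    position i); it is forced to the Watson-Crick complement of residue i
    with probability complementarity/100, otherwise drawn uniformly from
    ACGU (so even at 0% a mirrored position matches by chance 1/4 of the
    time).  G:U wobble never counts as complementary.  Total length is
    2*stem_len + loop_len.
    """
    if stem_len < 1 or loop_len < 0:
        raise ValueError("stem_len must be >= 1 and loop_len >= 0")
    if not (0 <= complementarity <= 100):
        raise ValueError("complementarity must lie in [0, 100]")
    arm5 = _random_arm(stem_len, rng)
    loop = _random_arm(loop_len, rng)
    if exact_count:
        n_forced = int(np.floor(complementarity / 100 * stem_len))
        forced = np.zeros(stem_len, dtype=bool)
        forced[rng.choice(stem_len, size=n_forced, replace=False)] = True
    else:
        forced = rng.random(stem_len) < complementarity / 100
    # 3' arm runs 3'-ward: its k-th residue mirrors 5' position stem_len - k
    arm3 = []
    random_fill = _random_arm(stem_len, rng)
    for k in range(stem_len):
        i = stem_len - 1 - k  # mirrored 5' index
        arm3.append(WC_COMPLEMENT[arm5[i]] if forced[i] else random_fill[k])
    return RnaSequence(id=seq_id, residues=arm5 + loop + "".join(arm3))


def mirrored_wc_fraction(seq: RnaSequence, stem_len: int, loop_len: int) -> float:
    """Fraction of mirrored arm positions that are Watson-Crick matched."""
    s = seq.residues
    if len(s) != 2 * stem_len + loop_len:
        raise ValueError("sequence length inconsistent with stem/loop geometry")
    hits = sum(
        1
        for i in range(stem_len)
        if s[2 * stem_len + loop_len - 1 - i] == WC_COMPLEMENT[s[i]]
    )
    return hits / stem_len


def _cell_rng(seed: int, stem_len: int, complementarity: int, replicate: int) -> np.random.Generator:
    """Deterministic per-cell stream, independent of iteration order."""
    return np.random.default_rng([seed & 0x7FFFFFFF, stem_len, complementarity, replicate])


def generate_catalog(spec: GeneratorSpec, fold_records: bool = True) -> HairpinCatalog:
    """Generate, fold and characterize the full hairpin population.

    One record per (stem length, complementarity, replicate) triple;
    byte-identical across runs with the same spec.  With
    ``fold_records=False`` the sequences are generated but not folded
    (delta_g/ape left at 0), useful for fast sequence-level checks.
    """
    records: list[HairpinRecord] = []
    for stem in spec.stem_lengths:
        for comp in spec.complementarities:
            for rep in range(spec.replicates):
                rng = _cell_rng(spec.seed, stem, comp, rep)
                sid = f"hp_s{stem}_c{comp}_r{rep}"
                seq = random_hairpin(
                    stem, spec.loop_len, comp, rng,
                    exact_count=spec.exact_count, seq_id=sid,
                )
                if fold_records:
                    rec = characterize_hairpin(seq, provenance="random")
                else:
                    rec = HairpinRecord(
                        sequence=seq,
                        structure=SecondaryStructure.from_dotbracket("." * len(seq)),
                        delta_g=0.0,
                        ape=0.0,
                        provenance="random",
                    )
                rec.metadata = {"stem_len": stem, "complementarity": comp, "replicate": rep}
                records.append(rec)
    return HairpinCatalog(spec=spec, records=records)


BACKBONE_STEM = 15
BACKBONE_LOOP = 5


def synth_backbone(
    n_hairpins: int,
    linker_len: int,
    rng: np.random.Generator,
) -> tuple[RnaSequence, SecondaryStructure]:
    """Genome-like backbone: strong hairpins joined by unpaired linkers.

    Concatenates ``n_hairpins`` fully complementary stem-loops (stem 15,
    loop 5) separated (and flanked) by pyrimidine linkers of
    ``linker_len`` nt, and returns the intended reference structure in
    which the designed stems are paired and linkers unpaired.  Pyrimidine
    linkers (C/U) cannot pair with each other, keeping them single-stranded
    in practice.
    """
    if n_hairpins < 0 or linker_len < 0:
        raise ValueError("n_hairpins and linker_len must be >= 0")
    parts: list[str] = []
    struct_parts: list[str] = []

    def linker() -> str:
        return "".join("CU"[k] for k in rng.integers(0, 2, size=linker_len))

    parts.append(linker())
    struct_parts.append("." * linker_len)
    for _ in range(n_hairpins):
        hp = random_hairpin(BACKBONE_STEM, BACKBONE_LOOP, 100, rng, seq_id="bb")
        parts.append(hp.residues)
        struct_parts.append("(" * BACKBONE_STEM + "." * BACKBONE_LOOP + ")" * BACKBONE_STEM)
        parts.append(linker())
        struct_parts.append("." * linker_len)
    seq = RnaSequence(id=f"backbone_n{n_hairpins}_l{linker_len}", residues="".join(parts))
    structure = SecondaryStructure.from_dotbracket("".join(struct_parts))
    return seq, structure
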