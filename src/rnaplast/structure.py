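"""Secondary-structure parsing and stem-loop mining.

Structures are held as a 1-based pair table (0 = unpaired), built from
dot-bracket (Vienna) notation or connectivity-table (CT) text.  The mining
operations extract the structural statistics used to characterize viral
genomes: simple hairpins (stem-loops with exactly one apical loop, allowing
bulges and internal loops but no multiloop branching), apical-loop counts,
maximal unpaired runs, and the longest uninterrupted helix.

Coordinates are 1-based inclusive throughout, matching the genome-position
conventions of the structure maps this module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequences import RnaSequence


class StructureError(ValueError):
    """Raised for malformed dot-bracket or CT input."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure as dot-bracket plus pair table.

    ``pair_table[i]`` (1-based, index 0 unused) is the partner of position i,
    or 0 if unpaired.
    """

    dotbracket: str
    pair_table: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    def __len__(self) -> int:
        return len(self.dotbracket)

    @classmethod
    def from_dotbracket(cls, text: str) -> "SecondaryStructure":
        """Parse dot-bracket notation (single '(' ')' bracket family).

        Pseudoknotted notations using additional bracket families are
        rejected; this is a documented limitation of the representation.
        """
        text = text.strip()
        if not text:
            raise StructureError("empty structure")
        n = len(text)
        pt = [0] * (n + 1)
        stack: list[int] = []
        for i, ch in enumerate(text, start=1):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {i}")
                j = stack.pop()
                pt[j] = i
                pt[i] = j
            elif ch != ".":
                raise StructureError(
                    f"unsupported symbol {ch!r} at position {i}; only '(', ')', '.' "
                    "are accepted (pseudoknot bracket families are not supported)"
                )
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1]}")
        return cls(dotbracket=text, pair_table=tuple(pt))

    @classmethod
    def from_pair_table(cls, pair_table: list[int] | tuple[int, ...]) -> "SecondaryStructure":
        """Build from a 1-based pair table (index 0 ignored), validating it."""
        pt = list(pair_table)
        n = len(pt) - 1
        db = []
        for i in range(1, n + 1):
            j = pt[i]
            if j == 0:
                db.append(".")
                continue
            if j == i:
                raise StructureError(f"position {i} pairs with itself")
            if not (1 <= j <= n) or pt[j] != i:
                raise StructureError(f"pair table not involutive at position {i}")
            db.append("(" if i < j else ")")
        struct = cls.from_dotbracket("".join(db))
        if list(struct.pair_table) != [0] + pt[1:]:
            raise StructureError("pair table contains crossing (pseudoknotted) pairs")
        return struct

    def pairs(self) -> list[tuple[int, int]]:
        """All base pairs (i, j) with i < j, in 5'-to-3' order of i."""
        return [(i, self.pair_table[i]) for i in range(1, self.length + 1)
                if self.pair_table[i] > i]

    def n_pairs(self) -> int:
        return len(self.pairs())


def parse_structure(text: str, fmt: str = "dot-bracket") -> SecondaryStructure:
    """Parse a structure from ``dot-bracket`` or ``ct`` text."""
    if fmt in ("dot-bracket", "dotbracket", "vienna"):
        # accept a Vienna block: optional sequence line before the structure
        lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith(">")]
        for ln in lines:
            token = ln.split()[0]
            if set(token) <= {"(", ")", "."}:
                return SecondaryStructure.from_dotbracket(token)
        raise StructureError("no dot-bracket line found")
    if fmt == "ct":
        seq, struct = parse_ct(text)
        return struct
    raise StructureError(f"unknown structure format {fmt!r}")


def parse_ct(text: str) -> tuple[str, SecondaryStructure]:
    """Parse standard 6-column CT text -> (sequence string, structure).

    Column layout per row: index, base, index-1, index+1, partner, index.
    A header row (count + title/energy) is optional; the energy field is
    ignored.
    """
    rows: list[tuple[int, str, int]] = []
    declared: int | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if declared is None and rows == []:
            # possible header: first token an integer count, rest a title
            try:
                idx = int(parts[0])
            except ValueError:
                raise StructureError(f"malformed CT line: {line!r}")
            if len(parts) >= 6:
                try:
                    int(parts[2]); int(parts[3]); int(parts[4]); int(parts[5])
                    is_row = len(parts[1]) == 1 and parts[1].isalpha()
                except ValueError:
                    is_row = False
            else:
                is_row = False
            if not is_row:
                declared = idx
                continue
        if len(parts) < 6:
            raise StructureError(f"CT row has fewer than 6 columns: {line!r}")
        idx, base, partner = int(parts[0]), parts[1], int(parts[4])
        rows.append((idx, base, partner))
    if not rows:
        raise StructureError("CT input contains no data rows")
    n = len(rows)
    if declared is not None and declared != n:
        raise StructureError(f"CT header declares {declared} rows, found {n}")
    pt = [0] * (n + 1)
    seq_chars = []
    for expect, (idx, base, partner) in enumerate(rows, start=1):
        if idx != expect:
            raise StructureError(f"CT rows out of order at row {expect} (index {idx})")
        if not (0 <= partner <= n):
            raise StructureError(f"CT partner {partner} out of range at row {idx}")
        pt[idx] = partner
        seq_chars.append(base.upper())
    for i in range(1, n + 1):
        if pt[i] and pt[pt[i]] != i:
            raise StructureError(f"conflicting pairs at positions {i} and {pt[i]}")
        if pt[i] == i:
            raise StructureError(f"position {i} pairs with itself")
    return "".join(seq_chars), SecondaryStructure.from_pair_table(pt)


def write_ct(seq: str, structure: SecondaryStructure, title: str = "") -> str:
    """Render sequence + structure as standard 6-column CT text."""
    if len(seq) != structure.length:
        raise StructureError("sequence and structure lengths differ")
    n = structure.length
    out = [f"{n} {title}".rstrip()]
    for i in range(1, n + 1):
        out.append(
            f"{i} {seq[i - 1]} {i - 1} {(i + 1) if i < n else 0} "
            f"{structure.pair_table[i]} {i}"
        )
    return "\n".join(out) + "\n"


@dataclass(frozen=True)
class HairpinMotif:
    """A simple hairpin (stem-loop) found in a larger structure.

    The span runs from the outermost 5' paired position to its 3' partner;
    inside there is exactly one hairpin (apical) loop, reached from the
    closing pair through stacked pairs, bulges and internal loops only.
    """

    start: int
    end: int
    n_pairs: int
    n_internal_loops: int
    n_bulges: int
    apical_loop_len: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def hairpin_loops(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """Closing pairs (i, j) of hairpin loops: no pairs strictly inside."""
    loops = []
    for i, j in structure.pairs():
        if all(structure.pair_table[k] == 0 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def count_apical_loops(structure: SecondaryStructure) -> int:
    """Number of hairpin (apical) loops in the structure."""
    return len(hairpin_loops(structure))


def find_simple_hairpins(
    structure: SecondaryStructure,
    min_stem_pairs: int = 3,
    max_loop_size: int | None = None,
) -> list[HairpinMotif]:
    """Extract maximal simple hairpins (one apical loop each).

    Starting from each hairpin loop's closing pair, the stem is grown
    outward through stacked pairs, bulges and internal loops; growth stops
    at a multiloop branch or the exterior loop.  ``max_loop_size`` (if set)
    additionally stops growth when either unpaired side of an internal
    loop/bulge exceeds that many residues.  Motifs with fewer than
    ``min_stem_pairs`` base pairs are dropped.  Returned motifs are disjoint
    and ordered by start position.
    """
    pt = structure.pair_table
    motifs = []
    for i0, j0 in hairpin_loops(structure):
        i, j = i0, j0
        n_pairs = 1
        n_internal = 0
        n_bulges = 0
        while True:
            # scan outward for the nearest enclosing pair with only
            # unpaired residues between it and the current pair
            a = i - 1
            while a >= 1 and pt[a] == 0:
                a -= 1
            b = j + 1
            while b <= structure.length and pt[b] == 0:
                b += 1
            if a < 1 or b > structure.length:
                break  # exterior loop
            if pt[a] != b:
                break  # multiloop branch (a and b pair elsewhere)
            left_gap = i - a - 1
            right_gap = b - j - 1
            if max_loop_size is not None and max(left_gap, right_gap) > max_loop_size:
                break
            if left_gap > 0 and right_gap > 0:
                n_internal += 1
            elif left_gap > 0 or right_gap > 0:
                n_bulges += 1
            i, j = a, b
            n_pairs += 1
        if n_pairs >= min_stem_pairs:
            motifs.append(
                HairpinMotif(
                    start=i,
                    end=j,
                    n_pairs=n_pairs,
                    n_internal_loops=n_internal,
                    n_bulges=n_bulges,
                    apical_loop_len=j0 - i0 - 1,
                )
            )
    motifs.sort(key=lambda m: m.start)
    return motifs


def unpaired_runs(structure: SecondaryStructure, min_run: int = 11) -> list[tuple[int, int]]:
    """Maximal runs of consecutive unpaired positions of length >= min_run.

    Returned as 1-based inclusive (start, end) intervals in 5'-to-3' order.
    """
    runs = []
    start = None
    pt = structure.pair_table
    for i in range(1, structure.length + 2):
        unpaired = i <= structure.length and pt[i] == 0
        if unpaired and start is None:
            start = i
        elif not unpaired and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    return runs


def longest_helix(structure: SecondaryStructure) -> int:
    """Length (in base pairs) of the longest uninterrupted stacked helix."""
    best = 0
    pt = structure.pair_table
    for i, j in structure.pairs():
        # count only from the outer end of a helix
        if i > 1 and pt[i - 1] == j + 1:
            continue
        run = 1
        while i + run < j - run and pt[i + run] == j - run:
            run += 1
        best = max(best, run)
    return best


@dataclass
class HairpinRecord:
    """One hairpin characterized by folding it in isolation."""

    sequence: RnaSequence
    structure: SecondaryStructure
    delta_g: float
    ape: float
    n_internal_loops: int = 0
    n_bulges: int = 0
    apical_loops: int = 0
    simple_hairpin: bool = False
    provenance: str = "mined"  # natural | designed | random | mined
    entropy: "object | None" = None  # EntropyProfile when available
    metadata: dict | None = None

    @property
    def length(self) -> int:
        return self.sequence.length


def characterize_hairpin(
    seq: RnaSequence,
    temperature: float = 37.0,
    provenance: str = "mined",
    entropy_base: float = 2.0,
) -> HairpinRecord:
    """Fold a candidate hairpin in isolation and summarize it.

    Records length, MFE free energy, whole-sequence APE, apical-loop count,
    internal-loop/bulge counts of the (single) stem-loop if present, and
    whether the MFE structure is one simple hairpin spanning a single
    stem-loop with no multiloop branching.
    """
    # local import to avoid a module cycle (fold.py imports SecondaryStructure)
    from .fold import average_positional_entropy, fold as _fold_seq, positional_entropy

    fr = _fold_seq(seq, temperature=temperature)
    profile = positional_entropy(fr, base=entropy_base)
    structure = fr.mfe_structure
    n_apical = count_apical_loops(structure)
    motifs = find_simple_hairpins(structure, min_stem_pairs=1)
    simple = n_apical == 1 and len(motifs) == 1
    n_internal = motifs[0].n_internal_loops if simple else 0
    n_bulges = motifs[0].n_bulges if simple else 0
    return HairpinRecord(
        sequence=seq,
        structure=structure,
        delta_g=fr.delta_g,
        ape=average_positional_entropy(profile),
        n_internal_loops=n_internal,
        n_bulges=n_bulges,
        apical_loops=n_apical,
        simple_hairpin=simple,
        provenance=provenance,
        entropy=profile,
    )
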