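"""Hairpin-insert design tools.

Turns the thermodynamic findings into decision rules:

* :func:`assess_retention` — classify a candidate hairpin as likely
  retained or likely lost in a viral backbone, from four checks: its MFE
  free energy sits inside (or above) the prediction band of the natural
  free-energy-vs-length regression; its global APE is low; no sliding PE
  window is hot; and its MFE conformation is a single simple hairpin.
* :func:`regional_ape_change` — fold a context with and without an insert
  and report how the insert changes average positional entropy around the
  insertion point.
* :func:`design_mimic` — stochastic local search over a hairpin's 3' arm
  (mismatches, bulge-creating deletions, loop edits) toward a target free
  energy, keeping the low-entropy single-hairpin phenotype.

The insertion convention is: "insert at position N" places the insert
immediately after residue N (1-based), so position 0 prepends.  The
thresholds defaults are heuristics calibrated to published retained/lost
exemplars, not physical constants; they are all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fold import fold as fold_sequence
from .fold import positional_entropy, sliding_window_ape
from .sequences import RnaSequence, WC_COMPLEMENT, reverse_complement
from .simulate import BASES
from .stats import DeltaGLengthRegressor, PredictionResult, RegressionFit, StatsError
from .structure import HairpinRecord, characterize_hairpin


class DesignError(ValueError):
    """Raised for invalid design inputs."""


class MimicDesignError(RuntimeError):
    """Raised when no acceptable mimic is found within the iteration budget."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class RetentionThresholds:
    """Cutoffs for the retention checks.

    ``ape_global_max`` bounds whole-hairpin APE; ``ape_window_len`` /
    ``ape_window_max`` bound every sliding-window mean PE (the "no hot
    region" rule); ``dg_band_level`` is the prediction-interval level for
    the free-energy band; ``require_simple_hairpin`` enables the topology
    check when a structure is available.
    """

    ape_global_max: float = 0.25
    ape_window_len: int = 15
    ape_window_max: float = 0.60
    dg_band_level: float = 0.95
    require_simple_hairpin: bool = True

    def __post_init__(self) -> None:
        if self.ape_global_max <= 0 or self.ape_window_max <= 0:
            raise DesignError("APE thresholds must be positive")
        if self.ape_window_len < 1:
            raise DesignError("window length must be >= 1")
        if not (0 < self.dg_band_level < 1):
            raise DesignError("band level must be in (0, 1)")


@dataclass
class CheckResult:
    name: str
    passed: bool
    measured: float
    bound: float
    note: str = ""


@dataclass
class RetentionAssessment:
    """Outcome of the retention checks for one candidate hairpin."""

    checks: dict[str, CheckResult] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "retained-likely" if all(c.passed for c in self.checks.values()) else "retained-unlikely"

    @property
    def reasons(self) -> list[str]:
        out = []
        for c in self.checks.values():
            status = "pass" if c.passed else "FAIL"
            out.append(f"{c.name}: {status} (measured {c.measured:.3f} vs bound {c.bound:.3f})"
                       + (f" — {c.note}" if c.note else ""))
        return out


def assess_retention(
    record: HairpinRecord,
    fit: RegressionFit,
    thresholds: RetentionThresholds = RetentionThresholds(),
) -> RetentionAssessment:
    """Apply the retention rules to one characterized hairpin.

    * ``dg_in_band``: the hairpin's free energy must be >= the lower bound
      of the level-``dg_band_level`` prediction interval of the natural
      regression at the hairpin's length (hairpins *more* stable than
      natural ones are the failure mode).  A free energy above the band's
      upper bound only triggers a warning, since weakly structured inserts
      are caught by the APE and topology checks.
    * ``ape_global``: whole-hairpin APE <= ``ape_global_max``.
    * ``ape_window``: every sliding ``ape_window_len``-nt mean PE <=
      ``ape_window_max``; requires a per-residue entropy profile (skipped
      with a warning if the record carries none).
    * ``topology``: the MFE structure is a single simple hairpin (skipped
      when ``require_simple_hairpin`` is off).
    """
    if fit.n < 3:
        raise StatsError("retention band requires a fit with n >= 3")
    est = DeltaGLengthRegressor.from_fit(fit, level=thresholds.dg_band_level)
    band = est.predict_interval(record.length)
    assess = RetentionAssessment()
    assess.checks["dg_in_band"] = CheckResult(
        name="dg_in_band",
        passed=record.delta_g >= band.lower,
        measured=record.delta_g,
        bound=band.lower,
        note=f"{int(thresholds.dg_band_level * 100)}% band ({band.lower:.1f}, {band.upper:.1f}) "
             f"at {record.length} nt",
    )
    if record.delta_g > band.upper:
        assess.warnings.append(
            f"delta_g {record.delta_g:.1f} above band upper bound {band.upper:.1f}: "
            "insert is less stable than natural hairpins of this length"
        )
    assess.checks["ape_global"] = CheckResult(
        name="ape_global",
        passed=record.ape <= thresholds.ape_global_max,
        measured=record.ape,
        bound=thresholds.ape_global_max,
    )
    if record.entropy is not None:
        if thresholds.ape_window_len > record.length:
            raise DesignError(
                f"window length {thresholds.ape_window_len} exceeds hairpin length {record.length}"
            )
        window_max = float(
            sliding_window_ape(record.entropy, thresholds.ape_window_len).max()
        )
        assess.checks["ape_window"] = CheckResult(
            name="ape_window",
            passed=window_max <= thresholds.ape_window_max,
            measured=window_max,
            bound=thresholds.ape_window_max,
            note=f"max {thresholds.ape_window_len}-nt window mean PE",
        )
    else:
        assess.warnings.append("no entropy profile on record; ape_window check skipped")
    if thresholds.require_simple_hairpin and record.structure is not None:
        assess.checks["topology"] = CheckResult(
            name="topology",
            passed=bool(record.simple_hairpin),
            measured=float(record.apical_loops),
            bound=1.0,
            note="MFE structure must be a single simple hairpin",
        )
    return assess


@dataclass(frozen=True)
class InsertionPlan:
    """An insert placed immediately after ``position`` (1-based) of a context."""

    context: RnaSequence
    position: int
    insert: RnaSequence | None
    region_radius: int = 30

    def __post_init__(self) -> None:
        if not (0 <= self.position <= self.context.length):
            raise DesignError(
                f"position {self.position} out of range 0..{self.context.length}"
            )
        if self.region_radius < 1:
            raise DesignError("region_radius must be >= 1")

    def modified_sequence(self) -> RnaSequence:
        ins = self.insert.residues if self.insert is not None else ""
        res = self.context.residues[: self.position] + ins + self.context.residues[self.position :]
        return RnaSequence(id=f"{self.context.id}+{self.insert.id if self.insert else 'empty'}"
                              f"@{self.position}", residues=res)


def regional_ape_change(
    plan: InsertionPlan,
    temperature: float = 37.0,
    entropy_base: float = 2.0,
) -> tuple[float, float, float]:
    """APE around the insertion point, before and after inserting.

    The region is the context residues within ``region_radius`` of the
    insertion point (up to radius residues on each side).  ``ape_before``
    averages their PE in the folded context; ``ape_after`` averages the PE
    of the same context residues plus all insert residues in the folded
    modified molecule.  Returns (ape_before, ape_after, delta).  An empty
    insert yields delta == 0 exactly.
    """
    ctx = plan.context
    lo = max(1, plan.position - plan.region_radius + 1)
    hi = min(ctx.length, plan.position + plan.region_radius)
    if hi < lo:
        raise DesignError("empty region: context too short for the chosen radius")
    before_profile = positional_entropy(
        fold_sequence(ctx, temperature=temperature), base=entropy_base
    )
    idx_before = np.arange(lo - 1, hi)
    ape_before = float(before_profile.values[idx_before].mean())

    ins_len = plan.insert.length if plan.insert is not None else 0
    if ins_len == 0:
        return ape_before, ape_before, 0.0
    after_profile = positional_entropy(
        fold_sequence(plan.modified_sequence(), temperature=temperature), base=entropy_base
    )
    # context residues keep their identity; those after the insertion shift
    idx_after = [i - 1 for i in range(lo, plan.position + 1)]
    idx_after += [plan.position + k for k in range(ins_len)]  # insert residues
    idx_after += [i - 1 + ins_len for i in range(plan.position + 1, hi + 1)]
    ape_after = float(after_profile.values[np.array(idx_after)].mean())
    return ape_before, ape_after, ape_after - ape_before


def recommended_dg(length: float, fit: RegressionFit, level: float = 0.95) -> PredictionResult:
    """Target free energy (and band) for a retained insert of the given length."""
    from .stats import predict_dg

    return predict_dg(fit, length, level=level)


DEFAULT_MIMIC_LOOP = "UAAC"  # tetraloop borrowed from a natural viral hairpin


def design_mimic(
    fixed_arm: RnaSequence,
    target_dg: float,
    tolerance: float,
    thresholds: RetentionThresholds = RetentionThresholds(),
    rng: np.random.Generator | None = None,
    max_iter: int = 500,
    loop: str = DEFAULT_MIMIC_LOOP,
    temperature: float = 37.0,
) -> tuple[HairpinRecord, list[dict]]:
    """Design a hairpin around a fixed 5' arm toward a target free energy.

    Starts from the fully complementary hairpin (fixed arm + loop + exact
    reverse complement) and performs greedy stochastic local search over
    the 3' side: mismatch substitutions, single-residue deletions (bulges),
    loop substitutions, and re-complementation moves.  The objective is
    lexicographic: first bring |delta_g - target_dg| within ``tolerance``,
    then reduce any global-APE / topology penalty while staying inside the
    free-energy window.  Succeeds on the first candidate inside the window
    that also passes the global-APE and topology checks; the
    (record, trace) pair is returned.  Raises
    :class:`MimicDesignError` when the budget is exhausted — the search
    never silently returns its best effort.

    Deterministic for a given ``rng`` state.
    """
    if fixed_arm.length < 10:
        raise DesignError("fixed arm must be at least 10 nt")
    if tolerance <= 0:
        raise DesignError("tolerance must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    arm = fixed_arm.residues
    loop_chars = list(loop)
    arm3 = list(reverse_complement(arm))  # mutable 3' side, 3'-ward order

    def build(k: int) -> RnaSequence:
        return RnaSequence(id=f"{fixed_arm.id}_mimic{k}",
                           residues=arm + "".join(loop_chars) + "".join(arm3))

    def score(seq: RnaSequence) -> tuple[tuple[float, float, float], HairpinRecord]:
        """Lexicographic objective: (excess |dG error| beyond tolerance,
        entropy/topology penalty, raw |dG error|) — first reach the free-
        energy window, then clean up plasticity while staying inside it."""
        rec = characterize_hairpin(seq, temperature=temperature, provenance="designed")
        err = abs(rec.delta_g - target_dg)
        penalty = max(0.0, rec.ape - thresholds.ape_global_max)
        if thresholds.require_simple_hairpin and not rec.simple_hairpin:
            penalty += 1.0
        return (max(err - tolerance, 0.0), penalty, err), rec

    def acceptable(s: tuple[float, float, float]) -> bool:
        return s[0] == 0.0 and s[1] == 0.0

    trace: list[dict] = []
    best_score, best_rec = score(build(0))
    trace.append({"iter": 0, "move": "start", "delta_g": best_rec.delta_g,
                  "err": best_score[2]})
    if acceptable(best_score):
        return best_rec, trace

    for it in range(1, max_iter + 1):
        saved_arm3, saved_loop = list(arm3), list(loop_chars)
        move = rng.choice(["mismatch", "delete", "loop", "restore"])
        if move == "mismatch" and len(arm3) > 0:
            k = int(rng.integers(0, len(arm3)))
            mirror = arm[min(len(arm) - 1, len(arm3) - 1 - k)]
            choices = [b for b in BASES if b != WC_COMPLEMENT[mirror]]
            arm3[k] = choices[int(rng.integers(0, len(choices)))]
        elif move == "delete" and len(arm3) > max(4, len(arm) // 2):
            del arm3[int(rng.integers(0, len(arm3)))]
        elif move == "loop" and loop_chars:
            k = int(rng.integers(0, len(loop_chars)))
            loop_chars[k] = BASES[int(rng.integers(0, 4))]
        elif move == "restore" and len(arm3) > 0:
            # re-complement one 3' position toward its mirror (re-stabilize)
            k = int(rng.integers(0, len(arm3)))
            mirror = arm[min(len(arm) - 1, len(arm3) - 1 - k)]
            arm3[k] = WC_COMPLEMENT[mirror]
        else:
            continue
        new_score, rec = score(build(it))
        if new_score < best_score:
            best_score, best_rec = new_score, rec
            trace.append({"iter": it, "move": str(move), "delta_g": rec.delta_g,
                          "err": new_score[2]})
            if acceptable(new_score):
                return rec, trace
        else:
            arm3, loop_chars = saved_arm3, saved_loop
    raise MimicDesignError(
        f"no acceptable hairpin within {tolerance} kcal/mol of target {target_dg} "
        f"(best |error| {best_score[2]:.2f} kcal/mol, residual penalty "
        f"{best_score[1]:.2f}, after {max_iter} proposals)",
        trace,
    )
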