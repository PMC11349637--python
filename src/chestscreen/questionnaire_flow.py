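"""The 16-item yes/no screening questionnaire as a branching flow.

The questionnaire reconstructs, from yes/no answers alone, exactly the
fields the decision table and the risk engine consume: sex assigned at
birth and identity spectrum, hormone exposure, chest surgical history,
age bracket, and the classical risk factors. Terminal states build both
profile objects and emit the *same* recommendation as the direct
classifiers — the flow adds no logic of its own.

Topology
--------
Items are a fixed set of 16 numbered questions forming a directed acyclic
graph. Most successors are static item ids; a few items are shared
between the two decision-table arms and carry per-arm successors,
resolved against the arm fixed by item 1 (the graph over (item, arm)
nodes is still acyclic and is verified by exhaustive traversal). The
transmasculine arm asks about surgery before anything else so a bilateral
mastectomy terminates the flow immediately — the matching row covers any
age and any risk, so no later answer could change the outcome.

Coarsenings relative to the direct API (documented, deliberate):

* ages collapse to the lowest integer consistent with the bracket
  answers (18, 25, 30 or 40);
* hormone exposure collapses to 0, 2.5 ("some, under 5 years") or 5.0
  ("5 years or more");
* a yes to item 16 maps to the 25-29/nulliparous parity category, the
  lower-risk category consistent with "first birth after 30, or none".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Mapping, Optional, Union

from .acr_decision import (
    Arm,
    DecisionConfig,
    DEFAULT_DECISION_CONFIG,
    ScreeningRecommendation,
    classify_variant,
    recommend,
)
from .errors import FlowUsageError, InternalConsistencyError
from .gail_engine import (
    DEFAULT_RISK_THRESHOLDS,
    GailRiskEstimate,
    RiskThresholds,
    estimate_risk,
)
from .profiles import (
    BiopsyCategory,
    ChestSurgery,
    FirstBirthCategory,
    GenderIdentity,
    HyperplasiaStatus,
    MenarcheCategory,
    RaceGroup,
    RelativesCategory,
    RiskFactorProfile,
    SexAssignedAtBirth,
    TransPatientProfile,
)

TERMINAL = "TERMINAL"
NextSpec = Union[int, Literal["TERMINAL"], Mapping[Arm, Union[int, Literal["TERMINAL"]]]]


@dataclass(frozen=True)
class QuestionnaireItem:
    id: int
    text: str
    #: raw answer field this item writes (consumed by the terminal builder)
    writes: str
    yes_next: NextSpec
    no_next: NextSpec


FLOW: dict[int, QuestionnaireItem] = {
    item.id: item
    for item in (
        QuestionnaireItem(1, "Were you assigned male at birth?", "amab", 2, 2),
        QuestionnaireItem(
            2,
            "Do you identify on the transfeminine spectrum?",
            "feminine_spectrum",
            {Arm.TRANSWOMAN: 3, Arm.TRANSMAN: 8},
            {Arm.TRANSWOMAN: 3, Arm.TRANSMAN: 8},
        ),
        QuestionnaireItem(
            3, "Have you ever used gender-affirming hormone therapy?", "hormones_ever", 4, 5
        ),
        QuestionnaireItem(
            4, "Has your hormone use totaled 5 years or more?", "hormones_ge5", 5, 5
        ),
        QuestionnaireItem(
            5,
            "Are you 25 years old or older?",
            "age_ge25",
            {Arm.TRANSWOMAN: 7, Arm.TRANSMAN: 6},
            10,
        ),
        QuestionnaireItem(6, "Are you 30 years old or older?", "age_ge30", 7, 10),
        QuestionnaireItem(7, "Are you 40 years old or older?", "age_ge40", 10, 10),
        QuestionnaireItem(
            8,
            'Have you had bilateral ("top") mastectomy surgery?',
            "mastectomy",
            TERMINAL,
            9,
        ),
        QuestionnaireItem(
            9, "Have you had breast-reduction surgery?", "breast_reduction", 5, 5
        ),
        QuestionnaireItem(
            10,
            "Has any first-degree relative (parent, sibling, child) had breast cancer?",
            "any_relative",
            11,
            12,
        ),
        QuestionnaireItem(
            11, "Have two or more first-degree relatives had breast cancer?", "relatives_ge2", 12, 12
        ),
        QuestionnaireItem(
            12,
            "Have you ever had a breast biopsy?",
            "any_biopsy",
            13,
            {Arm.TRANSWOMAN: TERMINAL, Arm.TRANSMAN: 15},
        ),
        QuestionnaireItem(13, "Have you had two or more breast biopsies?", "biopsies_ge2", 14, 14),
        QuestionnaireItem(
            14,
            "Did any biopsy show atypical hyperplasia?",
            "hyperplasia",
            {Arm.TRANSWOMAN: TERMINAL, Arm.TRANSMAN: 15},
            {Arm.TRANSWOMAN: TERMINAL, Arm.TRANSMAN: 15},
        ),
        QuestionnaireItem(
            15, "Did your first menstrual period occur before age 12?", "menarche_lt12", 16, 16
        ),
        QuestionnaireItem(
            16,
            "Was your first live birth after age 30, or have you had no live birth?",
            "late_or_no_birth",
            TERMINAL,
            TERMINAL,
        ),
    )
}

FIRST_ITEM = 1


def item_count(flow: Mapping[int, QuestionnaireItem] = FLOW) -> int:
    """Number of distinct items in the flow (16 in the shipped instrument)."""
    return len(flow)


@dataclass(frozen=True)
class QuestionnaireState:
    """Immutable position in the flow plus accumulated raw answers."""

    current: Union[int, Literal["TERMINAL"]] = FIRST_ITEM
    answered: tuple[tuple[int, bool], ...] = ()

    @property
    def is_terminal(self) -> bool:
        return self.current == TERMINAL

    @property
    def answers(self) -> dict[str, bool]:
        """Raw field -> answer map (state is reconstructible from this)."""
        return {FLOW[i].writes: a for i, a in self.answered}

    @property
    def arm(self) -> Optional[Arm]:
        amab = self.answers.get("amab")
        if amab is None:
            return None
        return Arm.TRANSWOMAN if amab else Arm.TRANSMAN


@dataclass(frozen=True)
class TerminalResult:
    """Everything a completed questionnaire session produces."""

    recommendation: ScreeningRecommendation
    trans_profile: TransPatientProfile
    risk_profile: RiskFactorProfile
    estimate: Optional[GailRiskEstimate]
    answered: tuple[tuple[int, bool], ...]


def _resolve_next(spec: NextSpec, arm: Optional[Arm]) -> Union[int, Literal["TERMINAL"]]:
    if isinstance(spec, Mapping):
        if arm is None:
            raise InternalConsistencyError(
                "arm-dependent successor reached before the arm was established"
            )
        return spec[arm]
    return spec


def build_profiles(
    answers: Mapping[str, bool],
) -> tuple[TransPatientProfile, RiskFactorProfile]:
    """Reconstruct both profile objects from the raw answer map.

    Unanswered fields take the lowest-risk / baseline-consistent value;
    natal history never asked on the transfeminine arm stays unknown.
    """
    amab = answers.get("amab", False)
    feminine = answers.get("feminine_spectrum", False)
    if amab:
        identity = (
            GenderIdentity.TRANSFEMININE if feminine else GenderIdentity.NONBINARY_AMAB
        )
        saab = SexAssignedAtBirth.MALE
    else:
        identity = (
            GenderIdentity.NONBINARY_AFAB if feminine else GenderIdentity.TRANSMASCULINE
        )
        saab = SexAssignedAtBirth.FEMALE

    if answers.get("age_ge40"):
        age = 40
    elif answers.get("age_ge30"):
        age = 30
    elif answers.get("age_ge25"):
        age = 25
    else:
        age = 18

    if answers.get("hormones_ge5"):
        hormones = 5.0
    elif answers.get("hormones_ever"):
        hormones = 2.5
    else:
        hormones = 0.0

    if answers.get("mastectomy"):
        surgery = ChestSurgery.BILATERAL_MASTECTOMY
    elif answers.get("breast_reduction"):
        surgery = ChestSurgery.BREAST_REDUCTION
    else:
        surgery = ChestSurgery.NONE

    trans_profile = TransPatientProfile(
        gender_identity=identity,
        sex_assigned_at_birth=saab,
        age=age,
        hormone_duration_years=hormones,
        chest_surgery=surgery,
    )

    if answers.get("relatives_ge2"):
        relatives = RelativesCategory.GE_2
    elif answers.get("any_relative"):
        relatives = RelativesCategory.ONE
    else:
        relatives = RelativesCategory.NONE
    if answers.get("biopsies_ge2"):
        biopsies = BiopsyCategory.GE_2
    elif answers.get("any_biopsy"):
        biopsies = BiopsyCategory.ONE
    else:
        biopsies = BiopsyCategory.NONE
    if "hyperplasia" in answers and biopsies is not BiopsyCategory.NONE:
        hyperplasia = (
            HyperplasiaStatus.PRESENT if answers["hyperplasia"] else HyperplasiaStatus.ABSENT
        )
    else:
        hyperplasia = HyperplasiaStatus.UNKNOWN
    if "menarche_lt12" in answers:
        menarche = MenarcheCategory.LT_12 if answers["menarche_lt12"] else MenarcheCategory.GE_14
    else:
        menarche = MenarcheCategory.UNKNOWN
    if "late_or_no_birth" in answers:
        first_birth = (
            FirstBirthCategory.AGE_25_29_OR_NULLIPAROUS
            if answers["late_or_no_birth"]
            else FirstBirthCategory.LT_20
        )
    else:
        first_birth = FirstBirthCategory.UNKNOWN

    risk_profile = RiskFactorProfile(
        current_age=age,
        age_at_menarche=menarche,
        age_at_first_live_birth=first_birth,
        n_biopsies=biopsies,
        atypical_hyperplasia=hyperplasia,
        n_first_degree_relatives=relatives,
        race_group=RaceGroup.OTHER_UNKNOWN,
    )
    return trans_profile, risk_profile


def _terminal_result(
    state: QuestionnaireState,
    config: DecisionConfig,
    thresholds: RiskThresholds,
) -> TerminalResult:
    trans_profile, risk_profile = build_profiles(state.answers)
    if trans_profile.chest_surgery is ChestSurgery.BILATERAL_MASTECTOMY:
        # Early exit: the mastectomy row covers any risk, so no tier is
        # computed (the risk items were never asked).
        estimate = None
        variant = classify_variant(trans_profile, config=config)
        rec = recommend(variant, profile=trans_profile, config=config)
    else:
        estimate = estimate_risk(risk_profile, thresholds=thresholds)
        variant = classify_variant(
            trans_profile,
            two_tier=estimate.two_tier,
            three_tier=estimate.three_tier,
            config=config,
        )
        rec = recommend(
            variant,
            profile=trans_profile,
            two_tier=estimate.two_tier,
            three_tier=estimate.three_tier,
            config=config,
        )
    return TerminalResult(
        recommendation=rec,
        trans_profile=trans_profile,
        risk_profile=risk_profile,
        estimate=estimate,
        answered=state.answered,
    )


def advance(
    state: QuestionnaireState,
    answer: bool,
    *,
    config: DecisionConfig = DEFAULT_DECISION_CONFIG,
    thresholds: RiskThresholds = DEFAULT_RISK_THRESHOLDS,
) -> Union[QuestionnaireState, TerminalResult]:
    """Apply one yes/no answer; returns the next state or the terminal result."""
    if state.is_terminal:
        raise FlowUsageError("cannot answer a terminal questionnaire state")
    item = FLOW[state.current]
    new_state = QuestionnaireState(
        current=state.current, answered=state.answered + ((item.id, bool(answer)),)
    )
    target = _resolve_next(item.yes_next if answer else item.no_next, new_state.arm)
    new_state = replace(new_state, current=target)
    if target == TERMINAL:
        return _terminal_result(new_state, config, thresholds)
    return new_state


def replay(
    answers: str | list[bool],
    *,
    config: DecisionConfig = DEFAULT_DECISION_CONFIG,
    thresholds: RiskThresholds = DEFAULT_RISK_THRESHOLDS,
) -> TerminalResult:
    """Machine mode: drive the flow from a Y/N answer string.

    Accepts a string over {Y, N} (case-insensitive; also 1/0) or a list
    of booleans, consumed in flow order. Branching means a session may
    use fewer than 16 answers; unused trailing answers are ignored. A
    string too short to reach a terminal is a usage error.
    """
    if isinstance(answers, str):
        mapping = {"y": True, "n": False, "1": True, "0": False}
        try:
            parsed = [mapping[c] for c in answers.strip().lower()]
        except KeyError as exc:
            raise FlowUsageError(f"unrecognized answer character {exc.args[0]!r}") from exc
    else:
        parsed = [bool(a) for a in answers]
    state: Union[QuestionnaireState, TerminalResult] = QuestionnaireState()
    for a in parsed:
        state = advance(state, a, config=config, thresholds=thresholds)
        if isinstance(state, TerminalResult):
            return state
    raise FlowUsageError(
        f"answer sequence exhausted after {len(parsed)} answers without "
        "reaching a terminal state"
    )


@dataclass(frozen=True)
class PathResult:
    answered: tuple[tuple[int, bool], ...]
    result: TerminalResult


def enumerate_paths(
    *,
    config: DecisionConfig = DEFAULT_DECISION_CONFIG,
    thresholds: RiskThresholds = DEFAULT_RISK_THRESHOLDS,
    flow: Mapping[int, QuestionnaireItem] = FLOW,
) -> list[PathResult]:
    """Exhaustive depth-first enumeration of every terminal path."""
    validate_flow(flow)
    results: list[PathResult] = []

    def walk(state: QuestionnaireState) -> None:
        for answer in (True, False):
            nxt = advance(state, answer, config=config, thresholds=thresholds)
            if isinstance(nxt, TerminalResult):
                results.append(PathResult(answered=nxt.answered, result=nxt))
            else:
                walk(nxt)

    walk(QuestionnaireState())
    return results


def validate_flow(flow: Mapping[int, QuestionnaireItem] = FLOW) -> None:
    """Build-time self-check of the flow graph.

    Verifies the shipped item count, that every successor id exists, that
    every item is reachable from item 1, that the (item, arm) graph is
    acyclic, and that every path reaches a terminal within the item
    budget.
    """
    if item_count(flow) != 16:
        raise InternalConsistencyError(
            f"flow must contain exactly 16 items (found {item_count(flow)})"
        )
    if FIRST_ITEM not in flow:
        raise InternalConsistencyError("flow has no first item")

    def successors(item: QuestionnaireItem, arm: Optional[Arm]):
        for spec in (item.yes_next, item.no_next):
            if isinstance(spec, Mapping):
                targets = [spec[arm]] if arm is not None else list(spec.values())
            else:
                targets = [spec]
            for t in targets:
                yield t

    reachable: set[int] = set()
    # DFS over (item, arm) nodes; arm is fixed by item 1's answer.
    for first_answer, arm in ((True, Arm.TRANSWOMAN), (False, Arm.TRANSMAN)):
        stack: list[tuple[int, tuple[int, ...]]] = []
        start = flow[FIRST_ITEM]
        reachable.add(FIRST_ITEM)
        target = _resolve_next(
            start.yes_next if first_answer else start.no_next, arm
        )
        if target != TERMINAL:
            stack.append((target, (FIRST_ITEM,)))
        while stack:
            node, path = stack.pop()
            if node in path:
                raise InternalConsistencyError(f"cycle through item {node} (arm {arm.value})")
            if node not in flow:
                raise InternalConsistencyError(f"dangling successor id {node}")
            if len(path) + 1 > item_count(flow):
                raise InternalConsistencyError(
                    f"path exceeds the {item_count(flow)}-item budget: {path + (node,)}"
                )
            reachable.add(node)
            for t in successors(flow[node], arm):
                if t != TERMINAL:
                    stack.append((t, path + (node,)))

    unreachable = set(flow) - reachable
    if unreachable:
        raise InternalConsistencyError(f"unreachable items: {sorted(unreachable)}")


# Self-check the shipped flow at import time.
validate_flow(FLOW)
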