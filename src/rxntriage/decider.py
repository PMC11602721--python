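"""Stage-wise pass/fail grading and campaign planning.

The decision-maker grades each reaction at each campaign stage from two
orthogonal branches of evidence — 1H NMR and (UPLC-)MS — and, by default,
requires both to pass (AND rule). A weighted combination
``w_nmr * s_nmr + w_ms * s_ms >= 1`` is available; the default equal weights
(0.5, 0.5) reproduce the pure AND rule. Stages whose criteria set a branch to
``none`` (e.g. MS-only grading of diversification and photochemistry
products) treat that branch as not applicable rather than as a pass or fail.

``plan_next`` turns a batch of stage decisions into the instruction list for
the synthesis platform: screen hits are scaled up (divergent campaigns) or
replicated six times (supramolecular campaigns), parity hits fan out into the
configured diversification reactions, and reproducible supramolecular hits
proceed to the guest-binding assay. Every decision is recorded in an
append-only log, including failures.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "Stage",
    "StageCriteria",
    "StageDecision",
    "Instruction",
    "Campaign",
    "DeciderError",
    "grade",
    "plan_next",
    "binding_matrix",
]


class DeciderError(ValueError):
    """Invalid criteria, missing evidence, or malformed campaign state."""


class Stage(str, Enum):
    SCREEN = "screen"
    SCALEUP_PARITY = "scaleup_parity"
    REPLICATE = "replicate"
    DIVERSIFY = "diversify"
    GUEST_ASSAY = "guest_assay"


_NMR_MODES = ("dtw", "peak_count", "shift_perturbation", "none")
_MS_MODES = ("targeted", "assembly_table", "none")


@dataclass(frozen=True)
class StageCriteria:
    """What counts as a hit at one stage."""

    stage: Stage
    nmr_mode: str = "dtw"
    ms_mode: str = "targeted"
    thresholds: Mapping[str, float] = field(default_factory=dict)
    combine: str = "AND"
    weights: tuple[float, float] = (0.5, 0.5)  # (nmr, ms), weighted mode only

    def __post_init__(self):
        if self.nmr_mode not in _NMR_MODES:
            raise DeciderError(f"unknown nmr_mode {self.nmr_mode!r}")
        if self.ms_mode not in _MS_MODES:
            raise DeciderError(f"unknown ms_mode {self.ms_mode!r}")
        if self.nmr_mode == "none" and self.ms_mode == "none":
            raise DeciderError("at least one evidence branch must be active")
        if self.combine not in ("AND", "weighted"):
            raise DeciderError(f"unknown combine rule {self.combine!r}")


@dataclass
class StageDecision:
    """Binary NMR/MS verdict pair and the combined verdict for one reaction."""

    reaction_id: str
    stage: Stage
    nmr_pass: bool | None  # None = branch not applicable
    ms_pass: bool | None
    overall: bool
    evidence: dict = field(default_factory=dict)
    replicate_index: int | None = None
    timestamp: str = ""

    def to_record(self) -> dict:
        rec = asdict(self)
        rec["stage"] = self.stage.value
        return rec


@dataclass(frozen=True)
class Instruction:
    """One next-step experiment for the synthesis platform."""

    kind: str  # scale_up | replicate | diversify | guest_assay
    reaction_id: str
    detail: str = ""

    def describe(self) -> str:
        extra = f" [{self.detail}]" if self.detail else ""
        return f"{self.kind}: {self.reaction_id}{extra}"


def _as_passed(evidence) -> bool:
    if evidence is None:
        raise DeciderError("required evidence branch is missing")
    if isinstance(evidence, bool):
        return evidence
    if hasattr(evidence, "passed"):
        return bool(evidence.passed)
    raise DeciderError(f"cannot interpret evidence object {type(evidence).__name__}")


def grade(
    reaction_id: str,
    nmr_evidence,
    ms_evidence,
    criteria: StageCriteria,
    replicate_index: int | None = None,
    timestamp: str | None = None,
) -> StageDecision:
    """Combine NMR and MS verdicts into one stage decision.

    Evidence may be a bool or any object with a ``passed`` attribute
    (e.g. :class:`~rxntriage.msproc.MsMatchResult`). A branch whose mode is
    ``none`` must not receive evidence used for the verdict; it is treated as
    not applicable. Under the default AND rule the reaction is a hit only if
    every applicable branch passed.
    """
    nmr_pass = None if criteria.nmr_mode == "none" else _as_passed(nmr_evidence)
    ms_pass = None if criteria.ms_mode == "none" else _as_passed(ms_evidence)
    applicable = [p for p in (nmr_pass, ms_pass) if p is not None]
    if criteria.combine == "AND":
        overall = all(applicable)
    else:
        w = {"nmr": criteria.weights[0], "ms": criteria.weights[1]}
        scores, weights = [], []
        if nmr_pass is not None:
            scores.append(1.0 if nmr_pass else 0.0)
            weights.append(w["nmr"])
        if ms_pass is not None:
            scores.append(1.0 if ms_pass else 0.0)
            weights.append(w["ms"])
        wsum = sum(weights)
        if wsum <= 0:
            raise DeciderError("weighted combine requires positive weights")
        overall = sum(s * wt for s, wt in zip(scores, weights)) / wsum >= 1.0 - 1e-12
    evidence = {}
    for name, ev in (("nmr", nmr_evidence), ("ms", ms_evidence)):
        if ev is None or isinstance(ev, bool):
            continue
        if hasattr(ev, "to_dict"):
            evidence[name] = ev.to_dict()
        elif hasattr(ev, "__dict__"):
            evidence[name] = {k: v for k, v in vars(ev).items() if _jsonable(v)}
    return StageDecision(
        reaction_id=reaction_id,
        stage=criteria.stage,
        nmr_pass=nmr_pass,
        ms_pass=ms_pass,
        overall=bool(overall),
        evidence=evidence,
        replicate_index=replicate_index,
        timestamp=timestamp
        if timestamp is not None
        else _dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class Campaign:
    """Staged campaign state: criteria per stage, registry, append-only log."""

    kind: str  # "divergent" | "supramolecular" | "ms_only"
    criteria: dict[Stage, StageCriteria]
    replicate_count: int = 6
    diversifications: Sequence[str] = ()
    guests: Sequence[str] = ()
    log: list[dict] = field(default_factory=list)

    def record(self, decision: StageDecision) -> None:
        self.log.append(decision.to_record())

    def record_all(self, decisions: Sequence[StageDecision]) -> None:
        for d in decisions:
            self.record(d)

    def logged_hits(self, stage: Stage) -> set[str]:
        return {
            r["reaction_id"]
            for r in self.log
            if r["stage"] == stage.value and r["overall"]
        }

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.log:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def plan_next(campaign: Campaign, decisions: Sequence[StageDecision]) -> list[Instruction]:
    """Instruction list implied by one batch of same-stage decisions.

    Screen hits -> scale-up (divergent) or ``replicate_count`` replicates each
    (supramolecular); parity hits -> every configured diversification;
    reproducible replicate groups -> guest assays over the guest set; terminal
    stages return no instructions. Failures generate nothing but stay logged.
    """
    if not decisions:
        return []
    stages = {d.stage for d in decisions}
    if len(stages) > 1:
        raise DeciderError(f"decisions span multiple stages: {sorted(s.value for s in stages)}")
    stage = stages.pop()
    if stage not in campaign.criteria:
        raise DeciderError(f"stage {stage.value!r} not configured for this campaign")
    out: list[Instruction] = []
    if stage is Stage.SCREEN:
        for d in decisions:
            if not d.overall:
                continue
            if campaign.kind == "supramolecular":
                out.extend(
                    Instruction("replicate", d.reaction_id, detail=f"replicate {k + 1}")
                    for k in range(campaign.replicate_count)
                )
            else:
                out.append(Instruction("scale_up", d.reaction_id))
    elif stage is Stage.SCALEUP_PARITY:
        for d in decisions:
            if d.overall:
                out.extend(
                    Instruction("diversify", d.reaction_id, detail=div)
                    for div in campaign.diversifications
                )
    elif stage is Stage.REPLICATE:
        by_reaction: dict[str, list[StageDecision]] = {}
        for d in decisions:
            by_reaction.setdefault(d.reaction_id, []).append(d)
        rule = str(campaign.criteria[stage].thresholds.get("replicate_rule", "all"))
        for rid, group in sorted(by_reaction.items()):
            if len(group) != campaign.replicate_count:
                raise DeciderError(
                    f"reaction {rid!r}: {len(group)} replicate decisions, "
                    f"expected {campaign.replicate_count}"
                )
            n_pass = sum(d.overall for d in group)
            ok = n_pass == len(group) if rule == "all" else n_pass * 2 > len(group)
            if ok:
                out.extend(
                    Instruction("guest_assay", rid, detail=g) for g in campaign.guests
                )
    elif stage in (Stage.DIVERSIFY, Stage.GUEST_ASSAY):
        return []
    else:  # pragma: no cover - Stage enum is closed
        raise DeciderError(f"unknown stage {stage!r}")
    return out


def binding_matrix(
    assays: Mapping[tuple[str, str], bool | tuple],
    hosts: Sequence[str],
    guests: Sequence[str],
) -> pd.DataFrame:
    """Boolean hosts x guests binding matrix from the guest-assay grid.

    ``assays`` maps (host, guest) to a verdict (bool, or a (bool, report)
    tuple from the shift-perturbation test). Missing cells raise with the full
    list of absentees. Row sums give bound-guest counts per host.
    """
    missing = [(h, g) for h in hosts for g in guests if (h, g) not in assays]
    if missing:
        raise DeciderError(f"missing assay cells: {missing}")
    data = {}
    for h in hosts:
        row = []
        for g in guests:
            v = assays[(h, g)]
            if isinstance(v, tuple):
                v = v[0]
            row.append(bool(v))
        data[h] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=list(guests))
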