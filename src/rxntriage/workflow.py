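"""End-to-end campaign runners: measurements in, decisions and plans out.

These functions replay a whole staged campaign over a measurement bundle
(real files loaded through :mod:`rxntriage.iohub`, or synthetic bundles from
:mod:`rxntriage.synthgen`): grade every reaction at the screening stage,
plan the follow-up experiments, grade those, and so on down to the binding
matrix or the diversification verdicts. The decision log records every
reaction at every stage, hits and failures alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import msproc, nmrproc
from .decider import Campaign, Instruction, Stage, StageCriteria, StageDecision, grade, plan_next

__all__ = [
    "SupramolecularParams",
    "DivergentParams",
    "SupramolecularResult",
    "DivergentResult",
    "run_supramolecular",
    "run_divergent",
]


@dataclass
class SupramolecularParams:
    """Thresholds for the supramolecular campaign stages."""

    count_tolerance: int = nmrproc.DEFAULT_COUNT_TOLERANCE
    shift_min: float = nmrproc.DEFAULT_SHIFT_MIN
    mz_tol: float = msproc.DEFAULT_MZ_TOL
    min_charge_states: int = 2
    parity_threshold: float = nmrproc.DEFAULT_PARITY_THRESHOLD
    change_threshold: float = nmrproc.DEFAULT_CHANGE_THRESHOLD
    line_broadening_hz: float = nmrproc.DEFAULT_LINE_BROADENING_HZ
    aromatic_window: tuple[float, float] = nmrproc.DEFAULT_AROMATIC_WINDOW
    replicate_rule: str = "all"  # or "majority"


@dataclass
class DivergentParams:
    """Thresholds for the divergent-synthesis campaign stages."""

    change_threshold: float = nmrproc.DEFAULT_CHANGE_THRESHOLD
    parity_threshold: float = nmrproc.DEFAULT_PARITY_THRESHOLD
    mz_tol: float = msproc.DEFAULT_MZ_TOL
    rel_area_min: float = msproc.DEFAULT_REL_AREA_MIN


@dataclass
class SupramolecularResult:
    campaign: Campaign
    screen_decisions: list[StageDecision]
    replicate_instructions: list[Instruction]
    replicate_decisions: list[StageDecision]
    assay_instructions: list[Instruction]
    binding: "object"  # pandas DataFrame hosts x guests
    hits: list[str] = field(default_factory=list)


@dataclass
class DivergentResult:
    campaign: Campaign
    screen_decisions: list[StageDecision]
    scaleup_instructions: list[Instruction]
    parity_decisions: list[StageDecision]
    diversify_instructions: list[Instruction]
    diversify_decisions: list[StageDecision]
    hits: list[str] = field(default_factory=list)


def _prep(spec, grid=None):
    return nmrproc.preprocess(spec, grid=grid)


def run_supramolecular(bundle, params: SupramolecularParams | None = None) -> SupramolecularResult:
    """Screen -> replicate -> guest-assay pipeline over one measurement bundle.

    Screening NMR uses the symmetric-product peak-count heuristic against the
    starting-material spectra; screening MS matches the direct-injection
    averaged spectrum against the precalculated assembly charge-ladder table
    (>= 2 charge states of one assembly required). Hits are replicated; each
    replicate must pass DTW parity against the screening spectrum plus the MS
    table test. Reproducible hosts enter the shift-perturbation guest assay.
    """
    p = params or SupramolecularParams()
    campaign = Campaign(
        kind="supramolecular",
        criteria={
            Stage.SCREEN: StageCriteria(Stage.SCREEN, "peak_count", "assembly_table"),
            Stage.REPLICATE: StageCriteria(
                Stage.REPLICATE, "dtw", "assembly_table",
                thresholds={"replicate_rule": p.replicate_rule},
            ),
            Stage.GUEST_ASSAY: StageCriteria(Stage.GUEST_ASSAY, "shift_perturbation", "none"),
        },
        replicate_count=bundle.replicate_count,
        guests=bundle.guests,
    )
    grid = nmrproc.default_grid()

    screen_decisions: list[StageDecision] = []
    prepped_screen: dict[str, nmrproc.NmrSpectrum] = {}
    for combo in bundle.combos:
        rxn = _prep(bundle.screen_nmr[combo], grid)
        prepped_screen[combo] = rxn
        sm = [_prep(s, grid) for s in bundle.sm_nmr[combo]]
        rxn_peaks = nmrproc.pick_peaks(rxn)
        sm_peaks = [nmrproc.pick_peaks(s) for s in sm]
        nmr_ok = nmrproc.symmetric_product_test(
            rxn_peaks, sm_peaks, count_tolerance=p.count_tolerance, shift_min=p.shift_min
        )
        ms_res = msproc.match_assembly_table(
            bundle.screen_ms[combo].averaged_spectrum(),
            bundle.table,
            tol=p.mz_tol,
            min_charge_states=p.min_charge_states,
        )
        d = grade(combo, nmr_ok, ms_res, campaign.criteria[Stage.SCREEN])
        screen_decisions.append(d)
    campaign.record_all(screen_decisions)
    replicate_instructions = plan_next(campaign, screen_decisions)
    hits = sorted({i.reaction_id for i in replicate_instructions})

    replicate_decisions: list[StageDecision] = []
    for combo in hits:
        for k in range(bundle.replicate_count):
            rep = _prep(bundle.replicate_nmr[combo][k], grid)
            ok, res = nmrproc.parity_check(
                prepped_screen[combo], rep,
                parity_threshold=p.parity_threshold, change_threshold=p.change_threshold,
            )
            ms_res = msproc.match_assembly_table(
                bundle.replicate_ms[combo][k].averaged_spectrum(),
                bundle.table,
                tol=p.mz_tol,
                min_charge_states=p.min_charge_states,
            )
            d = grade(combo, ok, ms_res, campaign.criteria[Stage.REPLICATE], replicate_index=k)
            d.evidence["nmr"] = vars(res)
            replicate_decisions.append(d)
    campaign.record_all(replicate_decisions)
    assay_instructions = plan_next(campaign, replicate_decisions) if replicate_decisions else []

    hosts = sorted({i.reaction_id for i in assay_instructions})
    assays: dict[tuple[str, str], bool] = {}
    assay_decisions: list[StageDecision] = []
    for inst in assay_instructions:
        host, guest = inst.reaction_id, inst.detail
        bound, report = nmrproc.guest_binding_test(
            _prep(bundle.host_nmr[host], grid),
            _prep(bundle.guest_nmr[(host, guest)], grid),
            window=p.aromatic_window,
            lb_hz=p.line_broadening_hz,
            shift_min=p.shift_min,
        )
        assays[(host, guest)] = bound
        d = grade(f"{host}|{guest}", bound, None, campaign.criteria[Stage.GUEST_ASSAY])
        d.evidence["shift_report"] = report
        assay_decisions.append(d)
    campaign.record_all(assay_decisions)

    from .decider import binding_matrix

    matrix = binding_matrix(assays, hosts, bundle.guests) if hosts else None
    return SupramolecularResult(
        campaign=campaign,
        screen_decisions=screen_decisions,
        replicate_instructions=replicate_instructions,
        replicate_decisions=replicate_decisions,
        assay_instructions=assay_instructions,
        binding=matrix,
        hits=hits,
    )


def run_divergent(bundle, params: DivergentParams | None = None) -> DivergentResult:
    """Screen -> scale-up parity -> diversification pipeline.

    Screening requires both a DTW chemical change from the summed
    starting-material spectra and the anticipated condensation-product mass
    among the main UPLC peaks. Scale-ups must pass a tighter DTW parity with
    the screening spectrum plus the same MS test; diversification products are
    graded on UPLC-MS alone.
    """
    p = params or DivergentParams()
    campaign = Campaign(
        kind="divergent",
        criteria={
            Stage.SCREEN: StageCriteria(Stage.SCREEN, "dtw", "targeted"),
            Stage.SCALEUP_PARITY: StageCriteria(Stage.SCALEUP_PARITY, "dtw", "targeted"),
            Stage.DIVERSIFY: StageCriteria(Stage.DIVERSIFY, "none", "targeted"),
        },
        diversifications=bundle.diversifications,
    )
    grid = nmrproc.default_grid()

    screen_decisions: list[StageDecision] = []
    prepped_screen: dict[str, nmrproc.NmrSpectrum] = {}
    for rid in bundle.reactions:
        rxn = _prep(bundle.screen_nmr[rid], grid)
        prepped_screen[rid] = rxn
        sm_sum = nmrproc.combine_references([_prep(s, grid) for s in bundle.sm_nmr[rid]])
        changed, res = nmrproc.chemical_change(rxn, sm_sum, threshold=p.change_threshold)
        ms_res = msproc.match_targeted(
            bundle.screen_lcms[rid], bundle.expected_mz[rid],
            tol=p.mz_tol, rel_area_min=p.rel_area_min,
        )
        d = grade(rid, changed, ms_res, campaign.criteria[Stage.SCREEN])
        d.evidence["nmr"] = vars(res)
        screen_decisions.append(d)
    campaign.record_all(screen_decisions)
    scaleup_instructions = plan_next(campaign, screen_decisions)
    hits = sorted({i.reaction_id for i in scaleup_instructions})

    parity_decisions: list[StageDecision] = []
    for rid in hits:
        scl = _prep(bundle.scaleup_nmr[rid], grid)
        ok, res = nmrproc.parity_check(
            prepped_screen[rid], scl,
            parity_threshold=p.parity_threshold, change_threshold=p.change_threshold,
        )
        ms_res = msproc.match_targeted(
            bundle.scaleup_lcms[rid], bundle.expected_mz[rid],
            tol=p.mz_tol, rel_area_min=p.rel_area_min,
        )
        d = grade(rid, ok, ms_res, campaign.criteria[Stage.SCALEUP_PARITY])
        d.evidence["nmr"] = vars(res)
        parity_decisions.append(d)
    campaign.record_all(parity_decisions)
    diversify_instructions = plan_next(campaign, parity_decisions) if parity_decisions else []

    diversify_decisions: list[StageDecision] = []
    for inst in diversify_instructions:
        key = (inst.reaction_id, inst.detail)
        ms_res = msproc.match_targeted(
            bundle.diversify_lcms[key], bundle.diversify_expected[key],
            tol=p.mz_tol, rel_area_min=p.rel_area_min,
        )
        d = grade(f"{inst.reaction_id}|{inst.detail}", None, ms_res, campaign.criteria[Stage.DIVERSIFY])
        diversify_decisions.append(d)
    campaign.record_all(diversify_decisions)

    return DivergentResult(
        campaign=campaign,
        screen_decisions=screen_decisions,
        scaleup_instructions=scaleup_instructions,
        parity_decisions=parity_decisions,
        diversify_instructions=diversify_instructions,
        diversify_decisions=diversify_decisions,
        hits=hits,
    )
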