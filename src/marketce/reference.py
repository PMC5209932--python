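"""Published values of the Croatian GT1 case study, for reproduction reports.

These are the figures printed in the published health-economic analysis
this package re-implements (EUR 2015, 10 000 Monte Carlo runs).  They are
used ONLY to annotate reproduction reports with a pass/tolerance status -
never inside the computation itself.

Scenario-level values depend on the pre-entry market mix and on the
composition of the experienced population across history/cirrhosis cells,
neither of which was published; the tolerances below are correspondingly
loose for those entries.  The cost-per-SVR cell for the new entrant in
naive/GT1a/cirrhosis patients is printed as 95 200 in the source, while
direct division of the printed inputs (90 000 / 0.946) gives 95 137 ->
95 100 at EUR 100 rounding; that cell is therefore documented as not
reproducible from the printed inputs and carries the computed value here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceValue", "REFERENCE_VALUES"]


@dataclass(frozen=True)
class ReferenceValue:
    key: str
    description: str
    value: float
    units: str
    rel_tol: float  # relative tolerance for the pass flag
    abs_tol: float = 0.0


REFERENCE_VALUES: tuple[ReferenceValue, ...] = (
    ReferenceValue(
        "cps_new_naive_1a_nocirr",
        "new entrant cost/SVR, naive GT1a no cirrhosis (EUR 100 rounding)",
        46_900, "EUR", 0.0,
    ),
    ReferenceValue(
        "cps_new_relapser_1a_nocirr",
        "new entrant cost/SVR, relapser GT1a no cirrhosis",
        47_900, "EUR", 0.0,
    ),
    ReferenceValue(
        "cps_new_null_1a_nocirr",
        "new entrant cost/SVR, null responder GT1a no cirrhosis",
        47_200, "EUR", 0.0,
    ),
    ReferenceValue(
        "cps_new_partial_1b_cirr",
        "new entrant cost/SVR, partial responder GT1b cirrhosis",
        52_500, "EUR", 0.0,
    ),
    ReferenceValue(
        "cps_boc_null_nocirr",
        "BOC+pegIFN mean cost/SVR, null responders no cirrhosis (MC)",
        108_800, "EUR", 0.005,
    ),
    ReferenceValue(
        "pct_svr_scenario0", "mean % achieving SVR, pre-entry market", 69, "%", 0.0, 5.0
    ),
    ReferenceValue(
        "pct_svr_scenario1", "mean % achieving SVR, scenario 1", 83, "%", 0.0, 5.0
    ),
    ReferenceValue(
        "pct_svr_scenario4", "mean % achieving SVR, full takeover", 98, "%", 0.0, 5.0
    ),
    ReferenceValue(
        "pct_cost_increase_scenario4",
        "expenditure increase at full takeover vs pre-entry market",
        43, "%", 0.25,
    ),
    ReferenceValue(
        "delta_cost_scenario4_meur",
        "mean additional annual cost at full takeover",
        1.4, "million EUR", 0.25,
    ),
    ReferenceValue(
        "icer_scenario1", "ICER of the smallest market expansion", 21_000, "EUR/SVR", 0.25
    ),
    ReferenceValue(
        "icer_scenario4", "ICER of full market takeover", 52_000, "EUR/SVR", 0.25
    ),
)
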