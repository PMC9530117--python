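"""Consolidated validation: every headline model and pipeline behaviour.

`run_full_validation` re-derives, from the packaged model and freshly
generated synthetic data, the checks the package is built around:

* the 30-cell phenotype specification table;
* the double-mutant bifurcation (two fixpoints, HOXA9 overactive in the
  JAK2-first branch, silent in the TET2-first branch);
* RUNX1's invariance to JAK2 activation after TET2 loss, and its
  responsiveness on a TET2 wild-type background;
* the double-mutant gene-level contrast (RUNX1/KLF1/GATA1 up, MYC down in
  JAK2-first);
* all three HOXA9 self-loop ablations (bifurcation abolished; the
  compensated variant additionally harbours a SPI1/GATA1 cycle);
* fixpoint-enumeration agreement between brute force and constraint
  propagation on random networks;
* recovery of the synthetic cohort structure by the stratification
  pipeline (bimodality rejected, cohort labels recovered, hazard ratio
  near truth).

Results are written as JSON plus a human-readable log; the seed is
embedded in both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

from .genotypes import check_specification
from .mpn import (
    AblationMode,
    ablate_self_loop,
    build_mpn_network,
    double_mutant_bifurcation,
    double_mutant_contrast,
    find_compensated_instability,
    mpn_specification,
    runx1_invariance_check,
    wildtype_state,
)
from .network import enumerate_fixpoints
from .stratify import run_stratification
from .synth import CohortSimConfig, RandomQNConfig, generate_bimodal_cohort, generate_random_qn


@dataclass(frozen=True)
class ValidationReport:
    checks: Dict[str, dict]
    seed: int

    @property
    def ok(self) -> bool:
        return all(c["passed"] for c in self.checks.values())


def _check_bifurcation(model) -> dict:
    atts = double_mutant_bifurcation(model)
    hox = sorted(a.fixpoint["HOXA9"] for a in atts if a.is_fixpoint)
    passed = len(atts) == 2 and hox == [0, 2]
    return {"passed": passed, "n_attractors": len(atts), "hoxa9_levels": hox}


def _check_runx1(model) -> dict:
    rep = runx1_invariance_check(model)
    return {
        "passed": rep.conclusive and rep.all_hold,
        "levels": rep.levels,
        "tet2_invariant": rep.tet2_invariant,
        "jak2_responsive_in_wt": rep.jak2_responsive_in_wt,
    }


def _check_contrast(model) -> dict:
    con = double_mutant_contrast(model)
    return {"passed": con.holds, "jak2_first": con.jak2_first, "tet2_first": con.tet2_first}


def _check_ablations(model) -> dict:
    detail = {}
    ok = True
    for mode in AblationMode:
        variant = ablate_self_loop(model, mode)
        atts = double_mutant_bifurcation(variant)
        hox = sorted({a.fixpoint["HOXA9"] for a in atts if a.is_fixpoint})
        entry = {"n_attractors": len(atts), "hoxa9_levels": hox}
        if mode is AblationMode.REMOVE:
            entry["passed"] = len(atts) == 1 and hox == [2]
        elif mode is AblationMode.BASAL_DEPENDENT:
            entry["passed"] = len(atts) == 1 and hox == [0]
        else:
            cyc = find_compensated_instability(variant)
            entry["cycle_period"] = None if cyc is None else cyc.period
            entry["passed"] = hox == [1] and cyc is not None
        ok = ok and entry["passed"]
        detail[mode.value] = entry
    return {"passed": ok, **detail}


def _check_enumeration(seed: int, n_models: int = 20) -> dict:
    agree = 0
    for i in range(n_models):
        cfg = RandomQNConfig(n_vars=5, edge_density=0.4, seed=seed * 1000 + i)
        model = generate_random_qn(cfg)
        if enumerate_fixpoints(model) == enumerate_fixpoints(model, propagate=True):
            agree += 1
    return {"passed": agree == n_models, "agree": agree, "n_models": n_models}


def _check_stratification(seed: int, n_boot: int = 200) -> dict:
    matrix, clinical, truth = generate_bimodal_cohort(CohortSimConfig(seed=seed))
    rep = run_stratification(matrix, clinical, n_boot=max(n_boot, 100), seed=seed)
    assigned = rep.cohorts.labels
    comparable = truth.index[matrix.loc["HOXA9"] > 0]
    agreement = float((assigned.loc[comparable] == truth.loc[comparable]).mean())
    passed = rep.bimodality_p < 0.05 and agreement >= 0.95
    return {
        "passed": passed,
        "bimodality_p": rep.bimodality_p,
        "label_agreement": agreement,
        "n_low": rep.cohorts.n_low,
        "n_high": rep.cohorts.n_high,
        "logrank_p": rep.logrank_p,
        "hazard_ratio": rep.hazard.hr,
    }


def run_full_validation(
    output_dir: Optional[str] = None, seed: int = 0, model=None
) -> ValidationReport:
    """Run every check; optionally write validation.json and validation.log.

    A substituted `model` (e.g. an ablated variant) is validated in place
    of the packaged network, in which case the model-level checks are
    expected to fail — that is the point of the substitution.
    """
    model = model if model is not None else build_mpn_network(validate=False)
    rep = check_specification(model, mpn_specification(), wildtype_state(model))
    checks = {
        "table1": {
            "passed": rep.all_pass,
            "cells_pass": rep.n_pass,
            "cells_total": rep.n_total,
        }
    }
    checks["bifurcation"] = _check_bifurcation(model)
    checks["runx1_invariance"] = _check_runx1(model)
    checks["double_mutant_contrast"] = _check_contrast(model)
    if model.has_edge("HOXA9", "HOXA9", "activator"):
        checks["self_loop_ablations"] = _check_ablations(model)
    checks["fixpoint_enumeration"] = _check_enumeration(seed)
    checks["stratification_recovery"] = _check_stratification(seed)
    report = ValidationReport(checks=checks, seed=seed)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "validation.json").write_text(
            json.dumps({"seed": seed, "ok": report.ok, "checks": checks}, indent=2) + "\n"
        )
        lines = [f"validation seed={seed} ok={report.ok}"]
        for name, c in checks.items():
            lines.append(f"[{'PASS' if c['passed'] else 'FAIL'}] {name}: "
                         + ", ".join(f"{k}={v}" for k, v in c.items() if k != "passed"))
        (out / "validation.log").write_text("\n".join(lines) + "\n")
    return report
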