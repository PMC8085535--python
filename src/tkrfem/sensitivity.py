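"""Perturbation-grid driver and validation/variation metrics.

The sensitivity study perturbs one parameter at a time — collateral-ligament
attachment positions (5 mm shifts), reference strain (+-5/+-10%), stiffness
(+-10%), and femoral-component alignment (varus/valgus tilt, internal/
external rotation) — re-solves the gait cycle, and reports peak contact
pressures as relative percentile variations (VAR) against the unperturbed
reference model::

    VAR = (estimated - reference) / reference * 100.

Curve-level agreement between a predicted and a reference force history is
summarized by the VARs of their RMS, mean and (population) standard
deviation.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact import ConvergenceError, FoundationModel, peak_metrics, run_gait, settle_to_contact
from .geometry import AlignmentPerturbation
from .ligaments import perturb_attachments, scale_parameter

__all__ = [
    "PerturbationSpec",
    "SensitivityRow",
    "CurveComparison",
    "var_pct",
    "round_half_up",
    "build_perturbation_grid",
    "run_sensitivity",
    "compare_force_curves",
]


def var_pct(estimated: float, reference: float) -> float:
    """Relative percentile variation, ``(estimated - reference)/reference * 100``.

    Sign-preserving and computed at full precision; round only at
    presentation (:func:`round_half_up`, 2 decimals).
    """
    if reference == 0:
        raise ZeroDivisionError("var_pct undefined for zero reference")
    return (estimated - reference) / reference * 100.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (ties away from zero), for table presentation."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class PerturbationSpec:
    """One row of a sensitivity design.

    ``target`` is MCL, LCL, both, or femoral_component; ``kind`` one of
    attachment_shift (magnitude mm, with ``direction``), eps_r_scale /
    k_scale (signed percent), or varus / valgus / internal_rotation /
    external_rotation (degrees). ``label`` matches the reference-table row.
    """

    label: str
    target: str
    kind: str
    magnitude: float
    direction: str | None = None

    _ALIGNMENT_KINDS = ("varus", "valgus", "internal_rotation", "external_rotation")

    @property
    def is_alignment(self) -> bool:
        return self.kind in self._ALIGNMENT_KINDS

    @property
    def is_reference(self) -> bool:
        return self.kind == "reference"


@dataclass
class SensitivityRow:
    label: str
    P1: float
    P2: float
    VAR1: float
    VAR2: float
    converged: bool = True
    error: str = ""


@dataclass
class CurveComparison:
    RMS_var: float
    Mean_var: float
    STD_var: float


def build_perturbation_grid(design: str, custom: list | None = None) -> list[PerturbationSpec]:
    """The one-at-a-time designs of the sensitivity study.

    ``ligament_table`` — the 33 published ligament-parameter rows: for each
    of the AP/ML/PD directions a 5 mm shift of both ligaments, of the MCL in
    both directions and of the LCL in both directions; eps_r scalings of
    -5/+5/-10/+10% and k scalings of -10/+10% each applied to both, MCL-only
    and LCL-only. ``alignment_table`` — the 10 femoral-component rows:
    varus/valgus tilt of 1/3/5 deg, internal/external rotation of 1/5 deg.
    """
    if design == "custom":
        return list(custom or [])
    if design == "ligament_table":
        grid: list[PerturbationSpec] = []
        axis_dirs = {"AP": ("anterior", "posterior"), "ML": ("medial", "lateral"),
                     "PD": ("proximal", "distal")}
        for axis, (d1, d2) in axis_dirs.items():
            grid.append(PerturbationSpec(f"MCL+LCL {axis} 5 mm", "both",
                                         "attachment_shift", 5.0, d1))
            for lig in ("MCL", "LCL"):
                for d in (d1, d2):
                    grid.append(PerturbationSpec(f"{lig} {d} 5 mm", lig,
                                                 "attachment_shift", 5.0, d))
        for pct in (-5, 5, -10, 10):
            for tgt in ("MCL+LCL", "MCL", "LCL"):
                grid.append(PerturbationSpec(
                    f"{tgt} eps_r {pct:+d}%", "both" if tgt == "MCL+LCL" else tgt,
                    "eps_r_scale", float(pct)))
        for pct in (-10, 10):
            for tgt in ("MCL+LCL", "MCL", "LCL"):
                grid.append(PerturbationSpec(
                    f"{tgt} k {pct:+d}%", "both" if tgt == "MCL+LCL" else tgt,
                    "k_scale", float(pct)))
        return grid
    if design == "alignment_table":
        grid = []
        for mode, name in (("varus", "Varus tilt"), ("valgus", "Valgus tilt")):
            for deg in (1, 3, 5):
                grid.append(PerturbationSpec(f"{name} {deg} deg", "femoral_component",
                                             mode, float(deg)))
        for mode, name in (("internal_rotation", "Internal rotation"),
                           ("external_rotation", "External rotation")):
            for deg in (1, 5):
                grid.append(PerturbationSpec(f"{name} {deg} deg", "femoral_component",
                                             mode, float(deg)))
        return grid
    raise ValueError(f"unknown design {design!r}")


def apply_perturbation(model: FoundationModel, spec: PerturbationSpec) -> FoundationModel:
    """Independent perturbed copy of the model (no state leakage)."""
    if spec.is_reference:
        return model.with_ligaments(model.ligaments)
    if spec.is_alignment:
        return model.with_alignment(AlignmentPerturbation(spec.kind, spec.magnitude))
    bundles = []
    for b in model.ligaments:
        hit = spec.target == "both" or b.name == spec.target
        if not hit:
            bundles.append(b)
        elif spec.kind == "attachment_shift":
            bundles.append(perturb_attachments(b, spec.direction, spec.magnitude))
        elif spec.kind == "eps_r_scale":
            bundles.append(scale_parameter(b, "eps_r", spec.magnitude))
        elif spec.kind == "k_scale":
            bundles.append(scale_parameter(b, "k", spec.magnitude))
        else:
            raise ValueError(f"unknown perturbation kind {spec.kind!r}")
    return model.with_ligaments(bundles)


def run_sensitivity(
    base_model: FoundationModel, grid: list[PerturbationSpec], bc
) -> pd.DataFrame:
    """One row per spec: perturb, re-settle, run the gait cycle, take peak
    metrics and VARs against the unperturbed reference row. Per-row
    convergence failures are recorded without aborting the batch."""
    theta0 = float(bc.flexion[0])
    ref_model = apply_perturbation(base_model, PerturbationSpec("Reference configuration",
                                                                "none", "reference", 0.0))
    settle_to_contact(ref_model, theta=theta0)
    ref = peak_metrics(run_gait(ref_model, bc), bc)
    rows = [SensitivityRow("Reference configuration", ref["P1"], ref["P2"], 0.0, 0.0)]
    for spec in grid:
        model = apply_perturbation(base_model, spec)
        try:
            settle_to_contact(model, theta=theta0)
            m = peak_metrics(run_gait(model, bc), bc)
            rows.append(SensitivityRow(
                spec.label, m["P1"], m["P2"],
                var_pct(m["P1"], ref["P1"]), var_pct(m["P2"], ref["P2"]),
            ))
        except (ConvergenceError, ValueError) as exc:
            rows.append(SensitivityRow(spec.label, np.nan, np.nan, np.nan, np.nan,
                                       converged=False, error=str(exc)))
    return pd.DataFrame([r.__dict__ for r in rows])


def compare_force_curves(predicted, reference, population_std: bool = True) -> CurveComparison:
    """VARs of the RMS, mean and STD summaries of two force curves.

    Both series must already share a common time grid. STD defaults to the
    population definition (ddof=0); set ``population_std=False`` for the
    sample definition.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"series length mismatch: {p.shape} vs {r.shape}")
    ddof = 0 if population_std else 1
    rms = lambda x: float(np.sqrt(np.mean(x**2)))  # noqa: E731

    def safe_var(est, ref):
        # a degenerate summary (e.g. STD of a constant reference) has no
        # defined relative variation
        return var_pct(est, ref) if ref != 0 else float("nan")

    return CurveComparison(
        RMS_var=safe_var(rms(p), rms(r)),
        Mean_var=safe_var(float(np.mean(p)), float(np.mean(r))),
        STD_var=safe_var(float(np.std(p, ddof=ddof)), float(np.std(r, ddof=ddof))),
    )
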