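"""Bundled reference sensitivity tables for the TKR contact-pressure study.

These are the published peak tibiofemoral contact pressures (MPa) of the
reference subject-specific model during normal gait, at the 1st (20% stance)
and 2nd (80% stance) axial force peaks, together with the printed relative
percentile variations (VAR %, see :func:`tkrfem.sensitivity.var_pct`), for

* the one-at-a-time ligament-parameter design (attachment shifts of 5 mm,
  reference-strain scalings of +-5/+-10%, stiffness scalings of +-10%), and
* the femoral-component malalignment design (varus/valgus tilt 1/3/5 deg,
  internal/external rotation 1/5 deg),

plus the per-trial peak pressures of the five gait patterns. They serve as
arithmetic inputs (the VAR columns are recomputable from the pressure
columns) and as the row-label ground truth for the perturbation grids.

Each row maps label -> (P1, VAR1, P2, VAR2). One printed VAR cell
("External rotation 5 deg", VAR1 = 67.82) is inconsistent with its own
pressure column, which gives 67.92; :func:`check_var_consistency` flags it
as a presumed typesetting error.
"""

from __future__ import annotations

__all__ = [
    "REFERENCE_ROW",
    "LIGAMENT_TABLE",
    "ALIGNMENT_TABLE",
    "GAIT_TRIAL_PEAKS",
    "check_var_consistency",
]

#: Reference (unperturbed) configuration: P1, VAR1, P2, VAR2.
REFERENCE_ROW = ("Reference configuration", (2.93, 0.00, 6.22, 0.00))

#: Ligament-parameter design rows, in presentation order.
LIGAMENT_TABLE = {
    "MCL+LCL AP 5 mm": (2.84, -3.07, 5.22, -16.08),
    "MCL anterior 5 mm": (2.74, -6.48, 5.14, -17.36),
    "MCL posterior 5 mm": (2.93, 0.00, 6.34, 1.93),
    "LCL anterior 5 mm": (2.91, -0.68, 6.44, 3.54),
    "LCL posterior 5 mm": (2.93, 0.00, 6.08, -2.25),
    "MCL+LCL ML 5 mm": (2.93, 0.00, 6.33, 1.77),
    "MCL medial 5 mm": (2.93, 0.00, 6.89, 10.77),
    "MCL lateral 5 mm": (2.93, 0.00, 6.33, 1.77),
    "LCL medial 5 mm": (2.93, 0.00, 6.08, -2.25),
    "LCL lateral 5 mm": (2.93, 0.00, 6.08, -2.25),
    "MCL+LCL PD 5 mm": (2.93, 0.00, 6.68, 7.40),
    "MCL proximal 5 mm": (2.93, 0.00, 7.06, 13.50),
    "MCL distal 5 mm": (2.92, 0.00, 5.69, -8.52),
    "LCL proximal 5 mm": (2.93, 0.00, 6.08, -2.25),
    "LCL distal 5 mm": (2.93, 0.00, 6.08, -2.25),
    "MCL+LCL eps_r -5%": (2.93, 0.00, 6.28, 0.96),
    "MCL eps_r -5%": (2.93, 0.00, 6.26, 0.64),
    "LCL eps_r -5%": (2.93, 0.00, 6.08, -2.25),
    "MCL+LCL eps_r +5%": (2.82, -3.75, 5.71, -8.20),
    "MCL eps_r +5%": (2.93, 0.00, 6.11, -1.77),
    "LCL eps_r +5%": (2.93, 0.00, 6.08, -2.25),
    "MCL+LCL eps_r -10%": (2.93, 0.00, 6.28, 0.96),
    "MCL eps_r -10%": (2.93, 0.00, 6.35, 2.09),
    "LCL eps_r -10%": (2.93, 0.00, 6.08, -2.25),
    "MCL+LCL eps_r +10%": (2.93, 0.00, 6.27, 0.80),
    "MCL eps_r +10%": (2.93, 0.00, 6.71, 7.88),
    "LCL eps_r +10%": (2.93, 0.00, 6.08, -2.25),
    "MCL+LCL k -10%": (2.93, 0.00, 6.28, 0.96),
    "MCL k -10%": (2.93, 0.00, 6.21, -0.16),
    "LCL k -10%": (2.93, 0.00, 6.08, -2.25),
    "MCL+LCL k +10%": (2.93, 0.00, 6.21, -0.16),
    "MCL k +10%": (2.93, 0.00, 6.21, -0.16),
    "LCL k +10%": (2.93, 0.00, 6.08, -2.25),
}

#: Femoral-component malalignment design rows.
ALIGNMENT_TABLE = {
    "Varus tilt 1 deg": (2.88, -1.71, 7.83, 25.88),
    "Varus tilt 3 deg": (2.69, -8.19, 7.00, 12.54),
    "Varus tilt 5 deg": (3.14, 7.16, 10.10, 62.38),
    "Valgus tilt 1 deg": (2.78, -5.12, 6.01, -3.38),
    "Valgus tilt 3 deg": (2.73, -6.83, 5.49, -11.74),
    "Valgus tilt 5 deg": (2.68, -8.53, 4.72, -24.12),
    "Internal rotation 1 deg": (3.87, 32.08, 7.14, 14.79),
    "Internal rotation 5 deg": (8.98, 206.48, 14.50, 133.12),
    "External rotation 1 deg": (2.96, 1.02, 6.25, 0.48),
    "External rotation 5 deg": (4.92, 67.82, 8.39, 34.89),
}

#: Maximum contact pressures (MPa) per gait trial at the two axial peaks.
GAIT_TRIAL_PEAKS = {
    "ngait_og1": (2.93, 6.22),
    "mtpgait2": (3.21, 7.74),
    "crouch_og2": (4.39, 5.06),
    "bouncy4": (3.64, 7.85),
    "smooth1": (2.19, 3.80),
}


def check_var_consistency(table: dict, reference=REFERENCE_ROW[1]) -> list[dict]:
    """Recompute every VAR cell from the pressure columns and report rows
    whose printed VAR differs from the recomputed value (2-decimal half-up).

    For the bundled tables this flags three presentation glitches: the
    "External rotation 5 deg" first-peak cell (printed 67.82, recomputed
    67.92 — a presumed typo), the "MCL distal 5 mm" first-peak cell (printed
    0.00 although its pressure column reads 2.92, giving -0.34), and the
    "Varus tilt 5 deg" first-peak cell (printed 7.16 where 3.14/2.93 gives
    7.1672..%, i.e. 7.17 under half-up rounding — the original presentation
    appears truncated there).
    """
    from .sensitivity import round_half_up, var_pct

    p1_ref, _, p2_ref, _ = reference
    issues = []
    for label, (p1, var1, p2, var2) in table.items():
        r1 = round_half_up(var_pct(p1, p1_ref), 2)
        r2 = round_half_up(var_pct(p2, p2_ref), 2)
        if r1 != var1 or r2 != var2:
            issues.append(
                {"label": label, "printed": (var1, var2), "recomputed": (r1, r2)}
            )
    return issues
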