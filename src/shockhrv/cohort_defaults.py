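"""Default cohort parameterization: per-variable, per-group, per-time-point mean ± SD.

The defaults describe a realistic 20-pig hemorrhagic-shock experiment
(13 survivors, 7 non-survivors; non-survivors have no post-resuscitation
cells).  The hemodynamic and metabolic rows are anchored at typical
survivor/non-survivor contrasts at Shock30 (MAP 57±9 vs 43±7 mmHg, CI 2.6±0.5
vs 1.7±0.2 L/min/m², lactate 3.7±1.4 vs 7.2±2.4 mmol/L, base excess −2.3±2.8
vs −6.8±3.3 mmol/L, potassium 4.2±0.3 vs 5.3±0.6 mmol/L); their values at the
other time points are trajectories consistent with the qualitative time
course of such experiments (pressure
and flow fall during hemorrhage, partially recover with shock compensation,
and are restored by fluid resuscitation; lactate, potassium and the base
deficit move the opposite way).
"""

from __future__ import annotations

# (variable, group) -> {timepoint: (mean, sd)}.  Survivor rows span all ten
# time points, non-survivor rows end at Shock60.

_TP_S = (
    "Baseline", "Hemorrhage5", "Hemorrhage10", "Hemorrhage15",
    "Shock30", "Shock60", "R0", "R60", "R120", "R180",
)
_TP_NS = _TP_S[:6]


def _row(timepoints, cells):
    return {tp: cell for tp, cell in zip(timepoints, cells, strict=True)}


DEFAULT_CELLS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    # ---- HRV frequency domain (published summary cells) -----------------
    ("VLF_abs", "S"): _row(_TP_S, [
        (3.11, 3.48), (8.46, 9.38), (1.13, 1.08), (2.72, 2.47), (0.94, 1.46),
        (0.82, 1.18), (0.53, 0.4256), (1.35, 1.08), (2.17, 2.36), (2.10, 2.15)]),
    ("VLF_abs", "NS"): _row(_TP_NS, [
        (2.40, 3.63), (6.02, 6.09), (22.73, 32.07), (457.7, 1168.0),
        (1.54, 2.62), (0.53, 0.61)]),
    ("LF_abs", "S"): _row(_TP_S, [
        (5.06, 5.93), (12.44, 19.77), (21.8, 15.43), (2.23, 2.42), (1.87, 3.98),
        (1.88, 3.38), (0.84, 0.92), (2.06, 1.69), (2.98, 2.29), (3.35, 2.90)]),
    ("LF_abs", "NS"): _row(_TP_NS, [
        (5.25, 5.76), (13.69, 17.05), (54.25, 74.29), (851.0, 2176.0),
        (3.25, 5.76), (1.32, 1.89)]),
    ("HF_abs", "S"): _row(_TP_S, [
        (5.95, 5.94), (52.67, 144.1), (19.12, 43.95), (56.54, 93.15),
        (0.74, 1.07), (1.20, 1.47), (0.73, 0.57), (1.91, 0.54), (1.14, 0.59),
        (1.33, 0.79)]),
    ("HF_abs", "NS"): _row(_TP_NS, [
        (2.99, 3.10), (3309.0, 8044.0), (386.6, 754.3), (52.67, 144.1),
        (1.14, 1.04), (0.78, 0.88)]),
    ("VLF_pct", "S"): _row(_TP_S, [
        (16.30, 7.56), (24.9, 13.72), (21.8, 15.43), (26.0, 12.5), (24.1, 3.93),
        (17.8, 5.27), (20.82, 9.57), (23.36, 6.93), (25.55, 7.06), (24.91, 6.49)]),
    ("VLF_pct", "NS"): _row(_TP_NS, [
        (15.14, 5.70), (25.0, 14.12), (14.57, 6.27), (21.29, 19.7),
        (17.86, 5.43), (13.25, 7.18)]),
    ("LF_pct", "S"): _row(_TP_S, [
        (28.3, 17.19), (20.0, 12.1), (21.6, 12.76), (22.8, 13.46), (34.2, 16.07),
        (32.8, 14.77), (30.55, 11.4), (38.09, 12.23), (42.0, 14.76), (43.09, 13.35)]),
    ("LF_pct", "NS"): _row(_TP_NS, [
        (36.43, 14.11), (29.71, 11.47), (19.71, 18.74), (22.0, 10.34),
        (36.86, 11.89), (30.5, 19.43)]),
    ("HF_pct", "S"): _row(_TP_S, [
        (55.3, 24.15), (54.9, 24.73), (56.4, 27.31), (51.2, 21.38), (41.9, 15.67),
        (49.5, 18.45), (48.73, 15.21), (38.64, 14.71), (32.55, 15.26), (32.2, 14.26)]),
    ("HF_pct", "NS"): _row(_TP_NS, [
        (48.57, 19.28), (45.29, 18.92), (65.71, 24.5), (56.71, 25.71),
        (45.0, 16.41), (56.5, 25.96)]),
    ("LF_nu", "S"): _row(_TP_S, [
        (37.2, 25.75), (31.9, 23.35), (32.51, 23.51), (36.3, 21.48), (47.4, 20.61),
        (42.7, 20.03), (41.18, 15.43), (52.19, 16.41), (58.27, 19.87), (59.0, 18.01)]),
    ("LF_nu", "NS"): _row(_TP_NS, [
        (45.14, 19.41), (43.57, 17.8), (26.14, 24.48), (33.0, 20.55),
        (48.29, 16.88), (37.75, 25.14)]),
    ("HF_nu", "S"): _row(_TP_S, [
        (62.8, 25.75), (68.1, 23.35), (67.2, 23.51), (63.7, 21.48), (52.6, 20.61),
        (57.3, 20.03), (58.82, 15.43), (47.82, 16.41), (41.73, 19.87), (41.0, 18.01)]),
    ("HF_nu", "NS"): _row(_TP_NS, [
        (54.86, 19.41), (56.43, 17.8), (73.86, 24.48), (67.0, 20.55),
        (51.71, 16.88), (62.25, 25.14)]),
    ("LF_HF", "S"): _row(_TP_S, [
        (2.93, 4.86), (1.65, 2.40), (1.10, 1.22), (1.63, 2.11), (2.21, 2.24),
        (1.70, 1.69), (1.25, 0.71), (2.37, 1.93), (3.18, 2.50), (2.97, 1.90)]),
    ("LF_HF", "NS"): _row(_TP_NS, [
        (1.74, 1.47), (1.466, 1.18), (0.83, 1.12), (1.08, 1.01),
        (2.29, 2.12), (1.87, 1.92)]),
    # ---- hemodynamics / metabolism (Shock30 anchored; rest synthetic) ---
    ("MAP", "S"): _row(_TP_S, [
        (78.0, 9.0), (65.0, 10.0), (55.0, 10.0), (48.0, 9.0), (57.0, 9.0),
        (60.0, 10.0), (75.0, 10.0), (72.0, 10.0), (70.0, 10.0), (68.0, 10.0)]),
    ("MAP", "NS"): _row(_TP_NS, [
        (77.0, 9.0), (60.0, 10.0), (50.0, 9.0), (42.0, 8.0), (43.0, 7.0),
        (40.0, 8.0)]),
    ("CI", "S"): _row(_TP_S, [
        (3.5, 0.6), (2.6, 0.5), (2.1, 0.4), (1.8, 0.4), (2.6, 0.5),
        (2.4, 0.5), (3.6, 0.6), (3.4, 0.6), (3.3, 0.6), (3.2, 0.6)]),
    ("CI", "NS"): _row(_TP_NS, [
        (3.5, 0.6), (2.4, 0.5), (1.8, 0.4), (1.4, 0.3), (1.7, 0.2),
        (1.5, 0.3)]),
    ("lactate", "S"): _row(_TP_S, [
        (1.5, 0.5), (1.8, 0.6), (2.3, 0.8), (2.8, 1.0), (3.7, 1.4),
        (4.0, 1.5), (3.5, 1.3), (2.8, 1.1), (2.2, 0.9), (1.9, 0.8)]),
    ("lactate", "NS"): _row(_TP_NS, [
        (1.6, 0.5), (2.2, 0.8), (3.4, 1.2), (5.2, 1.8), (7.2, 2.4),
        (8.5, 2.5)]),
    ("BE", "S"): _row(_TP_S, [
        (2.0, 2.0), (1.0, 2.2), (-0.2, 2.4), (-1.2, 2.6), (-2.3, 2.8),
        (-2.8, 2.8), (-2.0, 2.6), (-1.0, 2.4), (0.0, 2.2), (0.8, 2.0)]),
    ("BE", "NS"): _row(_TP_NS, [
        (1.8, 2.0), (0.2, 2.4), (-2.0, 2.8), (-4.5, 3.0), (-6.8, 3.3),
        (-8.0, 3.5)]),
    ("potassium", "S"): _row(_TP_S, [
        (3.9, 0.3), (4.0, 0.3), (4.0, 0.3), (4.1, 0.3), (4.2, 0.3),
        (4.3, 0.3), (4.2, 0.3), (4.1, 0.3), (4.0, 0.3), (4.0, 0.3)]),
    ("potassium", "NS"): _row(_TP_NS, [
        (4.0, 0.3), (4.2, 0.4), (4.5, 0.4), (4.9, 0.5), (5.3, 0.6),
        (5.8, 0.7)]),
    ("HR", "S"): _row(_TP_S, [
        (100.0, 15.0), (130.0, 20.0), (150.0, 22.0), (165.0, 25.0), (175.0, 25.0),
        (170.0, 25.0), (150.0, 22.0), (145.0, 22.0), (140.0, 20.0), (138.0, 20.0)]),
    ("HR", "NS"): _row(_TP_NS, [
        (102.0, 15.0), (135.0, 20.0), (160.0, 24.0), (180.0, 26.0), (190.0, 28.0),
        (185.0, 28.0)]),
}

#: Variables whose draws are truncated at zero (physiologically positive).
POSITIVE_VARIABLES: frozenset[str] = frozenset({
    "VLF_abs", "LF_abs", "HF_abs", "VLF_pct", "LF_pct", "HF_pct",
    "LF_nu", "HF_nu", "LF_HF", "MAP", "CI", "lactate", "potassium", "HR",
})
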