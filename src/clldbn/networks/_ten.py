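"""Treatment Effect Network (TEN): 18 nodes per slice, 6-month slices.

The TEN extends the health-status model with nodes describing the treatment
decision, the administered line of therapy (none, alkylating agents (AA),
purine analogs (PA) or monoclonal antibodies (MA)), its result
(CR+PR / SD / PD / death) and treatment- and complication-related mortality.

Provenance: the *Treatment result* transition CPT is the published expert
table, encoded exactly as printed (including its absorbing rows for
patients who died); the parent sets of *Treatment result* (printed CPT
header) and *Health* (published description: endurance, complications and
CLL stage) carry ``structure: paper``.  Every other CPT is a documented
placeholder built with the elicitation calculus; see docs/methods.md.
"""

from __future__ import annotations

from ..core import DynamicBayesianNetwork
from ._build import NO, YES, NetworkBuilder, bern, det

YN = (YES, NO)
STAGES = ("0", "I–II", "III–IV")
PROGNOSES = ("Good", "Intermediate", "Poor")
ECOG = ("ECOG 0–2", "ECOG 3–4")
AGES = ("≤ 65 years", "> 65 years")
SEXES = ("Female", "Male")
TREATMENTS = ("None", "AA", "PA", "MA")
RESULTS = ("CR+PR", "SD", "PD", "Death")
DECISIONS = ("Treatment", "Watch and wait", "Death")
PSTATES = ("Good", "Poor")
BREAKS = ("≤ 6 months", "> 6 months")

# published expert CPT: P(Treatment result@t | Treatment@t-1, Survival@t-1),
# columns in RESULTS order
TREATMENT_RESULT_TABLE = {
    ("None", YES): (0.01, 0.95, 0.04, 0.00),
    ("AA", YES): (0.60, 0.21, 0.19, 0.00),
    ("PA", YES): (0.75, 0.10, 0.15, 0.00),
    ("MA", YES): (0.72, 0.25, 0.03, 0.00),
    ("None", NO): (0.00, 0.00, 0.00, 1.00),
    ("AA", NO): (0.00, 0.00, 0.00, 1.00),
    ("PA", NO): (0.00, 0.00, 0.00, 1.00),
    ("MA", NO): (0.00, 0.00, 0.00, 1.00),
}

# placeholder treatment choice given a decision to treat:
# (patient's state, previous treatment) -> distribution over TREATMENTS
_TREAT_CHOICE = {
    ("Good", "None"): (0.0, 0.2, 0.5, 0.3),
    ("Good", "AA"): (0.0, 0.1, 0.6, 0.3),
    ("Good", "PA"): (0.0, 0.2, 0.3, 0.5),
    ("Good", "MA"): (0.0, 0.3, 0.5, 0.2),
    ("Poor", "None"): (0.0, 0.6, 0.2, 0.2),
    ("Poor", "AA"): (0.0, 0.3, 0.4, 0.3),
    ("Poor", "PA"): (0.0, 0.5, 0.2, 0.3),
    ("Poor", "MA"): (0.0, 0.5, 0.3, 0.2),
}

# placeholder decision policy given (CLL stage, progression) for a living patient
_DECISION_ALIVE = {
    ("0", NO): (0.05, 0.95, 0.0),
    ("0", YES): (0.60, 0.40, 0.0),
    ("I–II", NO): (0.25, 0.75, 0.0),
    ("I–II", YES): (0.80, 0.20, 0.0),
    ("III–IV", NO): (0.60, 0.40, 0.0),
    ("III–IV", YES): (0.95, 0.05, 0.0),
}

# placeholder per-slice probability of death from treatment toxicity
_TOXICITY = {"None": 0.0, "AA": 0.010, "PA": 0.015, "MA": 0.012}


def build_ten() -> DynamicBayesianNetwork:
    b = NetworkBuilder("ten", survival_variable="Survival")

    b.variable("Age", AGES, "Patient's age (up to 65 years or above)")
    b.variable(
        "Break between treatments",
        BREAKS,
        "Time that has elapsed after the previous treatment was applied",
    )
    b.variable("CLL stage", STAGES, "CLL stage according to the Rai staging system")
    b.variable(
        "Complications", YN, "Other cancers, infections, autoimmune complications, Richter syndrome"
    )
    b.variable("Death from complications", YN, "Patient died as a result of complications")
    b.variable("Death from treatment", YN, "Patient died as a result of treatment complications")
    b.variable("Decision", DECISIONS, "Results of analysis regarding necessity of treatment initiation")
    b.variable(
        "Endurance",
        YN,
        "Patient is alive or died due to reasons other than CLL and treatment complications",
    )
    b.variable("Health", ECOG, "Patient's general health condition according to ECOG performance status")
    b.variable(
        "Patient's state", PSTATES, "Parameter which decides whether more aggressive treatments are applicable"
    )
    b.variable("Previous treatment", TREATMENTS, "Previous-line treatment (the same values as in Treatment node)")
    b.variable(
        "Previous treatment result",
        RESULTS,
        "Result of the previous-line treatment (the same values as in Treatment result node)",
    )
    b.variable("Prognosis", PROGNOSES, "Synthetic prognosis based on analysis of cytogenetic parameters")
    b.variable("Progression", YN, "The applied treatment has resulted in progression of the disease or not")
    b.variable("Sex", SEXES, "Patient's gender")
    b.variable("Survival", YN, "Patient is alive or died (regardless of the cause of death)")
    b.variable(
        "Treatment",
        TREATMENTS,
        "Current-line treatment: alkylating agents (AA), purine analogs (PA) or monoclonal antibodies (MA)",
    )
    b.variable(
        "Treatment result",
        RESULTS,
        "Result of the current-line treatment: complete or partial remission (CR+PR), "
        "stabilization (SD), progression (PD)",
    )

    # ------------------------------------------------- prior slice (diagnosis)
    b.prior_cpt("Age", [], {(): (0.35, 0.65)})
    b.prior_cpt("Sex", [], {(): (0.37, 0.63)})
    b.prior_cpt("Prognosis", [], {(): (0.40, 0.40, 0.20)})
    b.prior_cpt(
        "CLL stage",
        [("Prognosis", 0)],
        {
            ("Good",): (0.65, 0.30, 0.05),
            ("Intermediate",): (0.40, 0.45, 0.15),
            ("Poor",): (0.20, 0.50, 0.30),
        },
    )
    b.prior_cpt("Complications", [], {(): bern(0.10)})
    b.prior_cpt("Death from complications", [], {(): det(YN, NO)})
    b.prior_cpt("Death from treatment", [], {(): det(YN, NO)})
    b.prior_cpt("Endurance", [], {(): det(YN, YES)})
    b.prior_cpt("Survival", [], {(): det(YN, YES)})
    b.prior_cpt(
        "Health",
        [("Complications", 0), ("CLL stage", 0)],
        {
            (YES, "0"): (0.75, 0.25),
            (YES, "I–II"): (0.65, 0.35),
            (YES, "III–IV"): (0.45, 0.55),
            (NO, "0"): (0.95, 0.05),
            (NO, "I–II"): (0.90, 0.10),
            (NO, "III–IV"): (0.75, 0.25),
        },
    )
    b.prior_cpt(
        "Patient's state",
        [("Health", 0), ("Age", 0)],
        {
            ("ECOG 0–2", "≤ 65 years"): (0.95, 0.05),
            ("ECOG 0–2", "> 65 years"): (0.80, 0.20),
            ("ECOG 3–4", "≤ 65 years"): (0.20, 0.80),
            ("ECOG 3–4", "> 65 years"): (0.05, 0.95),
        },
    )
    b.prior_cpt("Previous treatment", [], {(): det(TREATMENTS, "None")})
    b.prior_cpt("Previous treatment result", [], {(): det(RESULTS, "SD")})
    b.prior_cpt("Break between treatments", [], {(): det(BREAKS, "> 6 months")})
    b.prior_cpt("Progression", [], {(): bern(0.15)})
    b.prior_cpt(
        "Decision",
        [("CLL stage", 0), ("Progression", 0)],
        lambda stage, prog: _DECISION_ALIVE[(stage, prog)],
    )
    b.prior_cpt(
        "Treatment",
        [("Decision", 0), ("Patient's state", 0)],
        lambda dec, pstate: _TREAT_CHOICE[(pstate, "None")]
        if dec == "Treatment"
        else det(TREATMENTS, "None"),
    )
    b.prior_cpt("Treatment result", [], {(): (0.01, 0.95, 0.04, 0.00)})

    # ------------------------------------------------------- transition slice
    b.transition_cpt(
        "Age", [("Age", -1)], {("≤ 65 years",): (0.97, 0.03), ("> 65 years",): (0.0, 1.0)}
    )
    b.transition_cpt("Sex", [("Sex", -1)], lambda s: det(SEXES, s))
    b.transition_cpt(
        "Prognosis",
        [("Prognosis", -1)],
        {
            ("Good",): (0.97, 0.03, 0.00),
            ("Intermediate",): (0.00, 0.95, 0.05),
            ("Poor",): (0.00, 0.00, 1.00),
        },
    )
    b.transition_cpt(
        "Treatment result",
        [("Treatment", -1), ("Survival", -1)],
        TREATMENT_RESULT_TABLE,
        provenance="paper",
        structure="paper",
    )
    b.transition_cpt(
        "Previous treatment", [("Treatment", -1)], lambda tr: det(TREATMENTS, tr)
    )
    b.transition_cpt(
        "Previous treatment result",
        [("Treatment result", -1)],
        lambda res: det(RESULTS, res),
    )
    b.transition_cpt(
        "Break between treatments",
        [("Treatment", -1)],
        lambda tr: det(BREAKS, "> 6 months" if tr == "None" else "≤ 6 months"),
    )
    b.transition_cpt(
        "Progression",
        [("Treatment result", 0)],
        {
            ("CR+PR",): bern(0.05),
            ("SD",): bern(0.15),
            ("PD",): det(YN, YES),
            ("Death",): det(YN, NO),
        },
    )
    b.transition_cpt(
        "CLL stage",
        [("CLL stage", -1), ("Progression", 0)],
        {
            ("0", YES): (0.00, 0.90, 0.10),
            ("I–II", YES): (0.00, 0.10, 0.90),
            ("III–IV", YES): (0.00, 0.00, 1.00),
            ("0", NO): (0.95, 0.05, 0.00),
            ("I–II", NO): (0.05, 0.90, 0.05),
            ("III–IV", NO): (0.00, 0.10, 0.90),
        },
    )
    b.transition_cpt(
        "Complications",
        [("Complications", -1), ("Treatment", -1)],
        {
            (YES, "None"): bern(0.70),
            (YES, "AA"): bern(0.75),
            (YES, "PA"): bern(0.78),
            (YES, "MA"): bern(0.75),
            (NO, "None"): bern(0.05),
            (NO, "AA"): bern(0.10),
            (NO, "PA"): bern(0.12),
            (NO, "MA"): bern(0.10),
        },
    )
    # 0.018/slice = rescale of a 30%/10-year complication mortality; absorbing
    b.transition_cpt(
        "Death from complications",
        [("Complications", -1), ("Death from complications", -1)],
        {
            (YES, YES): det(YN, YES),
            (NO, YES): det(YN, YES),
            (YES, NO): bern(0.018),
            (NO, NO): det(YN, NO),
        },
    )
    b.transition_cpt(
        "Death from treatment",
        [("Treatment", -1), ("Death from treatment", -1)],
        lambda tr, prev: det(YN, YES) if prev == YES else bern(_TOXICITY[tr]),
    )
    # background (non-CLL, non-treatment) mortality; absorbing
    b.transition_cpt(
        "Endurance",
        [("Endurance", -1), ("Age", -1)],
        lambda end, age: det(YN, NO)
        if end == NO
        else (bern(1 - 0.004) if age == "≤ 65 years" else bern(1 - 0.018)),
    )
    b.transition_cpt(
        "Health",
        [("Endurance", 0), ("Complications", 0), ("CLL stage", 0)],
        lambda end, comp, stage: det(ECOG, "ECOG 3–4")
        if end == NO
        else {
            (YES, "0"): (0.70, 0.30),
            (YES, "I–II"): (0.60, 0.40),
            (YES, "III–IV"): (0.40, 0.60),
            (NO, "0"): (0.95, 0.05),
            (NO, "I–II"): (0.90, 0.10),
            (NO, "III–IV"): (0.70, 0.30),
        }[(comp, stage)],
        structure="paper",
    )
    b.transition_cpt(
        "Patient's state",
        [("Health", 0), ("Age", -1)],
        {
            ("ECOG 0–2", "≤ 65 years"): (0.95, 0.05),
            ("ECOG 0–2", "> 65 years"): (0.80, 0.20),
            ("ECOG 3–4", "≤ 65 years"): (0.20, 0.80),
            ("ECOG 3–4", "> 65 years"): (0.05, 0.95),
        },
    )
    b.transition_cpt(
        "Decision",
        [("CLL stage", -1), ("Progression", -1), ("Survival", -1)],
        lambda stage, prog, surv: det(DECISIONS, "Death")
        if surv == NO
        else _DECISION_ALIVE[(stage, prog)],
    )
    b.transition_cpt(
        "Treatment",
        [("Decision", 0), ("Patient's state", 0), ("Previous treatment", -1)],
        lambda dec, pstate, prev: _TREAT_CHOICE[(pstate, prev)]
        if dec == "Treatment"
        else det(TREATMENTS, "None"),
    )
    b.transition_cpt(
        "Survival",
        [
            ("Survival", -1),
            ("Endurance", 0),
            ("Death from complications", 0),
            ("Death from treatment", 0),
        ],
        lambda surv, end, dc, dt: det(
            YN, YES if (surv == YES and end == YES and dc == NO and dt == NO) else NO
        ),
    )
    return b.build()
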