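"""Health Status Network (HSN): 16 nodes per slice, 6-month slices.

The HSN predicts the health status of a CLL patient treated according to
best practice; treatment is not represented explicitly, only through the
transition probabilities of the health-related nodes.

Provenance rules for this definition:

- the *CLL stage* transition CPT is the published expert table, encoded
  exactly as printed (``provenance: paper``, ``structure: paper``);
- the *Death from other cancers* transition CPT is fully determined by the
  published worked elicitation (0 without other cancers, absorbing once
  dead, 0.007 per 6-month slice while another cancer is present —
  a 30%/25-year risk rescaled to one slice), so it also carries
  ``provenance: paper``;
- everything else is a documented placeholder (``provenance: placeholder``)
  with structure reconstructed from the published description where stated
  and ``structure: inferred`` otherwise.  Placeholder hazards were built
  with the elicitation calculus (see docs/methods.md) and are NOT the
  original authors' numbers.
"""

from __future__ import annotations

from ..core import DynamicBayesianNetwork
from ._build import NO, YES, NetworkBuilder, bern, det

YN = (YES, NO)
STAGES = ("III–IV", "I–II", "0")  # printed CPT column order
PROGNOSES = ("Good", "Intermediate", "Poor")
ECOG = ("ECOG 0–2", "ECOG 3–4")
AGES = ("≤ 65 years", "> 65 years")
SEXES = ("Female", "Male")

# published expert CPT for the CLL stage transition:
# rows keyed (Prognosis@t-1, CLL stage@t-1, CLL transformation@t),
# columns in STAGES order
CLL_STAGE_TABLE = {
    ("Good", "III–IV", YES): (1.00, 0.00, 0.00),
    ("Intermediate", "III–IV", YES): (1.00, 0.00, 0.00),
    ("Poor", "III–IV", YES): (1.00, 0.00, 0.00),
    ("Good", "I–II", YES): (1.00, 0.00, 0.00),
    ("Intermediate", "I–II", YES): (1.00, 0.00, 0.00),
    ("Poor", "I–II", YES): (1.00, 0.00, 0.00),
    ("Good", "0", YES): (1.00, 0.00, 0.00),
    ("Intermediate", "0", YES): (1.00, 0.00, 0.00),
    ("Poor", "0", YES): (1.00, 0.00, 0.00),
    ("Good", "III–IV", NO): (0.90, 0.10, 0.00),
    ("Intermediate", "III–IV", NO): (0.95, 0.05, 0.00),
    ("Poor", "III–IV", NO): (1.00, 0.00, 0.00),
    ("Good", "I–II", NO): (0.00, 0.80, 0.20),
    ("Intermediate", "I–II", NO): (0.05, 0.90, 0.05),
    ("Poor", "I–II", NO): (0.10, 0.90, 0.00),
    ("Good", "0", NO): (0.00, 0.00, 1.00),
    ("Intermediate", "0", NO): (0.00, 0.40, 0.60),
    ("Poor", "0", NO): (0.05, 0.95, 0.00),
}

# published worked elicitation for Death from other cancers:
# keyed (Other cancers@t-1, Death from other cancers@t-1)
DEATH_OTHER_CANCERS_TABLE = {
    (YES, YES): (1.0, 0.0),
    (NO, YES): (1.0, 0.0),
    (YES, NO): (0.007, 0.993),
    (NO, NO): (0.0, 1.0),
}


def build_hsn() -> DynamicBayesianNetwork:
    b = NetworkBuilder("hsn", survival_variable="Survival")

    b.variable("Age", AGES, "Patient's age (up to 65 years or above)")
    b.variable(
        "Autoimmune complications",
        YN,
        "Complications related to hematologic disorders, i.e. thrombocytopenia and anemia",
    )
    b.variable("CLL stage", STAGES, "CLL stage according to the Rai staging system")
    b.variable(
        "CLL transformation",
        YN,
        "Transformation of CLL into an aggressive form of leukemia, mainly Richter syndrome",
    )
    b.variable("Death", YN, "Patient died (regardless of the cause of death) — opposite to Survival")
    b.variable("Death from CLL transformation", YN, "Patient died as a result of transformation of CLL")
    b.variable("Death from infections", YN, "Patient died as a result of infections or is alive")
    b.variable("Death from other cancers", YN, "Patient died as a result of cancers other than CLL")
    b.variable(
        "Death from other causes",
        YN,
        "Patient died due to reasons other than CLL, CLL transformation, infections or other cancers",
    )
    b.variable("Endurance", YN, "Patient is alive or died due to reasons other than CLL")
    b.variable("Health", ECOG, "Patient's general health condition according to ECOG performance status")
    b.variable("Infections", YN, "Patient suffers from bacterial, viral or fungal infections")
    b.variable("Other cancers", YN, "Patient has other cancers besides CLL, e.g. colorectal cancer")
    b.variable("Prognosis", PROGNOSES, "Synthetic prognosis based on analysis of cytogenetic parameters")
    b.variable("Sex", SEXES, "Patient's gender")
    b.variable("Survival", YN, "Patient is alive or died (regardless of the cause of death) — opposite to Death")

    # ------------------------------------------------- prior slice (diagnosis)
    b.prior_cpt("Age", [], {(): (0.35, 0.65)})
    b.prior_cpt("Sex", [], {(): (0.37, 0.63)})
    b.prior_cpt("Prognosis", [], {(): (0.40, 0.40, 0.20)})
    b.prior_cpt(
        "CLL stage",
        [("Prognosis", 0)],
        {
            ("Good",): (0.05, 0.30, 0.65),
            ("Intermediate",): (0.15, 0.45, 0.40),
            ("Poor",): (0.30, 0.50, 0.20),
        },
    )
    b.prior_cpt("CLL transformation", [], {(): bern(0.005)})
    b.prior_cpt("Infections", [], {(): bern(0.10)})
    b.prior_cpt("Autoimmune complications", [], {(): bern(0.05)})
    b.prior_cpt("Other cancers", [], {(): bern(0.05)})
    for cause in (
        "Death from CLL transformation",
        "Death from infections",
        "Death from other cancers",
        "Death from other causes",
    ):
        b.prior_cpt(cause, [], {(): det(YN, NO)})  # alive at diagnosis
    b.prior_cpt(
        "Death",
        [
            ("Death from CLL transformation", 0),
            ("Death from infections", 0),
            ("Death from other cancers", 0),
            ("Death from other causes", 0),
        ],
        lambda a, c, d, e: det(YN, YES if YES in (a, c, d, e) else NO),
    )
    b.prior_cpt("Survival", [("Death", 0)], {(YES,): det(YN, NO), (NO,): det(YN, YES)})
    b.prior_cpt(
        "Endurance",
        [
            ("Death from infections", 0),
            ("Death from other cancers", 0),
            ("Death from other causes", 0),
        ],
        lambda i, c, o: det(YN, NO if YES in (i, c, o) else YES),
    )
    b.prior_cpt(
        "Health",
        [("Age", 0), ("Sex", 0)],
        {
            ("≤ 65 years", "Female"): (0.92, 0.08),
            ("≤ 65 years", "Male"): (0.90, 0.10),
            ("> 65 years", "Female"): (0.75, 0.25),
            ("> 65 years", "Male"): (0.72, 0.28),
        },
    )

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
    # Richter-type transformation: absorbing; incidence rises with poor prognosis
    b.transition_cpt(
        "CLL transformation",
        [("CLL transformation", -1), ("Prognosis", -1)],
        lambda prev, prog: det(YN, YES)
        if prev == YES
        else bern({"Good": 0.001, "Intermediate": 0.0025, "Poor": 0.005}[prog]),
    )
    b.transition_cpt(
        "CLL stage",
        [("Prognosis", -1), ("CLL stage", -1), ("CLL transformation", 0)],
        CLL_STAGE_TABLE,
        provenance="paper",
        structure="paper",
    )
    b.transition_cpt(
        "Infections",
        [("Infections", -1), ("Autoimmune complications", -1)],
        {
            (YES, YES): bern(0.55),
            (YES, NO): bern(0.40),
            (NO, YES): bern(0.25),  # odds_adjust(0.10, 3): infections ~3x more likely
            (NO, NO): bern(0.10),
        },
    )
    b.transition_cpt(
        "Autoimmune complications",
        [("Autoimmune complications", -1)],
        {(YES,): bern(0.80), (NO,): bern(0.03)},
    )
    b.transition_cpt(
        "Other cancers",
        [("Other cancers", -1)],
        {(YES,): det(YN, YES), (NO,): bern(0.005)},
    )
    b.transition_cpt(
        "Death from other cancers",
        [("Other cancers", -1), ("Death from other cancers", -1)],
        DEATH_OTHER_CANCERS_TABLE,
        provenance="paper",
        structure="paper",
    )
    # 0.010/slice = rescale of a 40%/25-year infection mortality; absorbing
    b.transition_cpt(
        "Death from infections",
        [("Infections", -1), ("Death from infections", -1)],
        {
            (YES, YES): det(YN, YES),
            (NO, YES): det(YN, YES),
            (YES, NO): bern(0.010),
            (NO, NO): det(YN, NO),
        },
    )
    # 0.173/slice = rescale of a 50%/2-year mortality after transformation
    b.transition_cpt(
        "Death from CLL transformation",
        [("CLL transformation", -1), ("Death from CLL transformation", -1)],
        {
            (YES, YES): det(YN, YES),
            (NO, YES): det(YN, YES),
            (YES, NO): bern(0.173),
            (NO, NO): det(YN, NO),
        },
    )
    b.transition_cpt(
        "Death from other causes",
        [("Age", -1), ("Sex", -1), ("Death from other causes", -1)],
        lambda age, sex, prev: det(YN, YES)
        if prev == YES
        else bern(
            {
                ("≤ 65 years", "Female"): 0.002,
                ("≤ 65 years", "Male"): 0.003,
                ("> 65 years", "Female"): 0.012,
                ("> 65 years", "Male"): 0.015,
            }[(age, sex)]
        ),
    )
    b.transition_cpt(
        "Endurance",
        [
            ("Death from infections", 0),
            ("Death from other cancers", 0),
            ("Death from other causes", 0),
        ],
        lambda i, c, o: det(YN, NO if YES in (i, c, o) else YES),
    )
    b.transition_cpt(
        "Health",
        [("Health", -1), ("Age", 0), ("Sex", 0), ("Survival", -1)],
        lambda h, age, sex, surv: det(ECOG, h)
        if surv == NO
        else (
            {
                ("ECOG 0–2", "≤ 65 years", "Female"): (0.94, 0.06),
                ("ECOG 0–2", "≤ 65 years", "Male"): (0.92, 0.08),
                ("ECOG 0–2", "> 65 years", "Female"): (0.86, 0.14),
                ("ECOG 0–2", "> 65 years", "Male"): (0.84, 0.16),
                ("ECOG 3–4", "≤ 65 years", "Female"): (0.26, 0.74),
                ("ECOG 3–4", "≤ 65 years", "Male"): (0.24, 0.76),
                ("ECOG 3–4", "> 65 years", "Female"): (0.11, 0.89),
                ("ECOG 3–4", "> 65 years", "Male"): (0.09, 0.91),
            }[(h, age, sex)]
        ),
    )
    b.transition_cpt(
        "Death",
        [
            ("Death from CLL transformation", 0),
            ("Death from infections", 0),
            ("Death from other cancers", 0),
            ("Death from other causes", 0),
        ],
        lambda a, c, d, e: det(YN, YES if YES in (a, c, d, e) else NO),
    )
    b.transition_cpt(
        "Survival", [("Death", 0)], {(YES,): det(YN, NO), (NO,): det(YN, YES)}
    )
    return b.build()
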