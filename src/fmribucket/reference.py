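"""Reference values printed by the motivating two-day fMRI study.

The study compared working-memory (2-back > 0-back) activation between
Gulf War illness and chronic fatigue syndrome cohorts before (Day 1) and
after (Day 2) an exercise stress test.  Its subject-level imaging data are
not deposited, but the printed summary tables are usable inputs: the nine
per-model validation accuracies for each day, and the AAL region lists
retained by the final ensembles.  These constants support worked-example
arithmetic (accuracy mean and population SD; region bookkeeping) and give
the reporting layer its target layout.
"""

from __future__ import annotations

import numpy as np

#: Per-model validation accuracy (percent), Day 1 = pre-exercise.
DAY1_ACCURACIES_PCT = {
    "k_nearest_neighbors": 70,
    "linear_svm": 70,
    "decision_tree": 82,
    "random_forest": 77,
    "adaboost": 69,
    "naive_bayes": 74,
    "quadratic_discriminant": 73,
    "logistic_regression": 82,
    "neural_net": 76,
}

#: Per-model validation accuracy (percent), Day 2 = post-exercise.
DAY2_ACCURACIES_PCT = {
    "k_nearest_neighbors": 81,
    "linear_svm": 77,
    "decision_tree": 82,
    "random_forest": 78,
    "adaboost": 81,
    "naive_bayes": 78,
    "quadratic_discriminant": 75,
    "logistic_regression": 82,
    "neural_net": 77,
}

#: AAL regions retained by the final ensembles of both days.
REGIONS_BOTH_DAYS = (
    "Angular_R",
    "Frontal_Inf_Tri_R",
    "Frontal_Mid_L",
    "Frontal_Mid_Orb_R",
    "Frontal_Mid_R",
    "Frontal_Sup_Orb_R",
    "Frontal_Sup_R",
    "Insula_R",
    "Occipital_Mid_L",
    "Parietal_Inf_L",
    "Parietal_Sup_L",
    "Parietal_Sup_R",
    "Postcentral_R",
    "Precuneus_L",
    "Precuneus_R",
    "Putamen_L",
    "Temporal_Inf_R",
)

#: Regions retained only by the Day 1 (pre-exercise) ensemble.
REGIONS_DAY1_ONLY = (
    "Cerebellum_Crus2_L",
    "Cingulum_Mid_L",
    "Cingulum_Mid_R",
    "Frontal_Inf_Oper_L",
    "Frontal_Inf_Orb_R",
    "Frontal_Mid_Orb_L",
    "Frontal_Sup_L",
    "Fusiform_R",
    "Occipital_Mid_R",
    "Rolandic_Oper_R",
    "SupraMarginal_L",
    "Temporal_Mid_R",
    "Temporal_Pole_Mid_L",
)

#: Regions retained only by the Day 2 (post-exercise) ensemble.
REGIONS_DAY2_ONLY = (
    "Cerebellum_6_L",
    "Cerebellum_8_R",
    "Cerebellum_9_L",
    "Cingulum_Ant_L",
    "Frontal_Inf_Oper_R",
    "Frontal_Inf_Orb_L",
    "Frontal_Sup_Medial_R",
    "Fusiform_L",
    "Parietal_Inf_R",
    "Postcentral_L",
    "Precentral_L",
    "Precentral_R",
    "Rolandic_Oper_L",
    "Supp_Motor_Area_L",
    "Temporal_Mid_L",
    "Thalamus_L",
)

REGIONS_DAY1 = REGIONS_BOTH_DAYS + REGIONS_DAY1_ONLY
REGIONS_DAY2 = REGIONS_BOTH_DAYS + REGIONS_DAY2_ONLY


def accuracy_summary(accuracies: dict[str, float]) -> tuple[float, float]:
    """Mean and population standard deviation of per-model accuracies."""
    values = np.array(list(accuracies.values()), dtype=float)
    return float(values.mean()), float(values.std(ddof=0))


def shared_regions(day1=REGIONS_DAY1, day2=REGIONS_DAY2) -> set[str]:
    return set(day1) & set(day2)
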