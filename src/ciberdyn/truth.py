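"""Ground-truth phenotype model for simulated screens.

Each guide carries a growth effect and a parametric ISR-activity surface

    a(d, t) = beta0 + A * d^h / (d^h + ec50^h) * f(t; tau, alpha)

where ``d`` is the stressor dose (uM sulfometuron methyl), ``t`` hours since
treatment, ``beta0`` the basal ISR shift after guide induction (log2 vs the
negative-control reference), ``A`` the inducible amplitude (log2), ``ec50``
and ``h`` the Hill dose-response parameters, and

    f(t) = (1 - exp(-t / tau)) * ((1 - alpha) + alpha * exp(-t / (3 tau)))

a saturating onset with time constant ``tau`` that, when the adaptation
fraction ``alpha`` is positive, decays back toward (1 - alpha) of its peak —
the transient-activation-then-recovery behaviour seen at sub-arresting
stress doses.  All activities are expressed relative to the wildtype
(negative-control) response at the same dose and time, so control guides
have an identically zero surface.

Guides belong to one of five qualitative classes:

* ``neutral`` — no effect (all negative controls are neutral).
* ``translation`` — knockdowns of tRNA charging/processing, Pol III, eIF2/
  eIF2B: slow growth with proportionate basal ISR activation
  (beta0 = -k * gamma, k > 0).
* ``pcl5_feedback`` — loss of the Pcl5 negative-feedback arm: ISR activation
  with no growth cost, brisk un-damped induction.
* ``ribi`` — ribosome-biogenesis knockdowns: reduced basal ISR, dose
  sensitivity shifted ~4.5-fold to higher stress, and slowed onset.
* ``proteasome`` — reduced basal ISR with a weaker, damped version of the
  ribi dose shift.

A dual-guide perturbation is additive: its activity surface is the sum of
the two single-guide surfaces plus an optional interaction term eta
(default 0), and its growth effect is the sum of the single growth effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import GuideLibrary, ParameterError

CLASSES = ("neutral", "translation", "pcl5_feedback", "ribi", "proteasome")

TRUTH_COLUMNS = [
    "guide_id",
    "class_label",
    "growth_effect",
    "basal_isr",
    "amplitude",
    "ec50",
    "hill",
    "onset_h",
    "adaptation",
]


class ConfigurationError(ValueError):
    """Inconsistent truth-model configuration."""


@dataclass
class TruthParams:
    """Tunable class-level effect sizes for the simulation ground truth.

    Defaults encode the qualitative screen phenotypes: translation-limiting
    guides couple basal ISR to growth (beta0 = -k*gamma), ribi guides shift
    the dose response 4.5-fold less sensitive and slow its onset, proteasome
    guides show a damped intermediate, and Pcl5-feedback loss activates the
    ISR at no growth cost.
    """

    class_fractions: dict = field(
        default_factory=lambda: {
            "neutral": 0.30,
            "translation": 0.30,
            "pcl5_feedback": 0.10,
            "ribi": 0.15,
            "proteasome": 0.15,
        }
    )
    ec50_translation: float = 0.5  # uM SM; low dose (0.56 uM) near half-max
    ribi_ec50_shift: float = 4.5  # fold decrease in dose sensitivity, in [4, 5]
    proteasome_ec50_shift: float = 2.0
    growth_isr_coupling: float = 2.0  # k in beta0 = -k * gamma (translation class)
    hill: float = 2.0
    gamma_range_translation: tuple = (-0.5, -0.1)
    gamma_range_ribi: tuple = (-0.5, -0.15)
    gamma_range_proteasome: tuple = (-0.35, -0.05)
    basal_range_pcl5: tuple = (0.8, 1.5)
    basal_range_ribi: tuple = (-1.5, -0.6)
    basal_range_proteasome: tuple = (-0.8, -0.3)
    amplitude_range: tuple = (1.5, 2.5)
    amplitude_range_pcl5: tuple = (2.0, 3.0)
    onset_fast_h: tuple = (0.3, 0.6)
    onset_ribi_h: tuple = (1.0, 1.5)
    onset_proteasome_h: tuple = (0.6, 1.0)
    adaptation_range: tuple = (0.0, 0.2)
    adaptation_range_proteasome: tuple = (0.2, 0.4)


def time_response(t, tau, alpha):
    """Saturating onset with optional adaptation; f(0)=0, f(inf)=1-alpha."""
    t = np.asarray(t, dtype=float)
    tau = np.asarray(tau, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rise = -np.expm1(-t / tau)
        damp = (1.0 - alpha) + alpha * np.exp(-t / (3.0 * tau))
    # tau == 0 is the instantaneous-onset limit: step to the adapted plateau.
    return np.where(tau > 0, rise * damp, (t > 0) * (1.0 - alpha))


def hill_response(dose, ec50, h):
    """Hill dose response in [0, 1); 0 at dose 0."""
    dose = np.asarray(dose, dtype=float)
    ec50 = np.asarray(ec50, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dh = np.power(dose, h)
        num = dh / (dh + np.power(ec50, h))
    return np.where(dose > 0, num, 0.0)


def reporter_response(activity, floor_log2: float = -5.0, ceiling_log2: float = 5.0):
    """Saturating reporter transfer from latent ISR activity to expression.

    A transcriptional reporter has a finite dynamic range: expression cannot
    exceed the promoter's fully induced output nor fall below its leaky
    floor.  The latent (additive) activity ``a`` is mapped through a smooth
    clamp in linear expression space,

        expr = 1 / (2**-a + 2**-ceiling) + 2**floor,

    which is monotone, ~identity in the middle of the range, and saturates
    at the ceiling/floor.  Dual-guide combinations of two strong activators
    therefore land within the range delineated by strong single guides
    rather than multiplying without bound.
    """
    a = np.asarray(activity, dtype=float)
    expr = 1.0 / (np.exp2(-a) + np.exp2(-ceiling_log2)) + np.exp2(floor_log2)
    return np.log2(expr)


def activity_surface(basal, amplitude, ec50, hill, onset_h, adaptation, dose, time_h):
    """Evaluate a(d, t) = beta0 + A * Hill(d) * f(t) (vectorized)."""
    return np.asarray(basal, dtype=float) + np.asarray(amplitude, dtype=float) * hill_response(
        dose, ec50, hill
    ) * time_response(time_h, onset_h, adaptation)


@dataclass
class TruthModel:
    """Per-guide ground-truth parameters plus pairwise interaction terms."""

    guides: pd.DataFrame  # TRUTH_COLUMNS, indexed by guide_id
    interactions: dict = field(default_factory=dict)  # (guide_a, guide_b) sorted -> eta

    def __post_init__(self):
        missing = set(TRUTH_COLUMNS) - set(self.guides.columns)
        if missing:
            raise ConfigurationError(f"truth table missing columns: {sorted(missing)}")
        if self.guides.index.name != "guide_id":
            self.guides = self.guides.set_index("guide_id", drop=False)

    def params(self, guide_id: str) -> pd.Series:
        try:
            return self.guides.loc[guide_id]
        except KeyError as exc:
            raise ConfigurationError(f"no truth assigned for guide {guide_id!r}") from exc

    def eta(self, guide_a: str, guide_b: str) -> float:
        return float(self.interactions.get(tuple(sorted((guide_a, guide_b))), 0.0))

    def activity(self, guide_id, dose, time_h):
        """Single-guide ISR activity (log2 vs controls) at (dose, time)."""
        p = self.params(guide_id)
        return activity_surface(
            p.basal_isr, p.amplitude, p.ec50, p.hill, p.onset_h, p.adaptation, dose, time_h
        )

    def pair_activity(self, guide_a, guide_b, dose, time_h):
        """Dual-guide activity: sum of singles plus interaction eta."""
        return (
            self.activity(guide_a, dose, time_h)
            + self.activity(guide_b, dose, time_h)
            + self.eta(guide_a, guide_b)
        )

    def growth(self, guide_id: str) -> float:
        return float(self.params(guide_id).growth_effect)

    def pair_growth(self, guide_a: str, guide_b: str) -> float:
        return self.growth(guide_a) + self.growth(guide_b)


def _assign_classes(
    library: GuideLibrary,
    fractions: dict,
    rng: np.random.Generator,
    class_assignment: dict | None,
) -> dict:
    """Assign a dynamics class per gene (all guides of a gene share a class)."""
    if class_assignment is not None:
        out = {}
        for g in library.guides:
            key = g.guide_id if g.guide_id in class_assignment else g.gene
            if key not in class_assignment and not g.is_negative_control:
                raise ConfigurationError(f"guide {g.guide_id} has no class assignment")
            out[g.guide_id] = "neutral" if g.is_negative_control else class_assignment[key]
        return out
    labels = list(fractions)
    probs = np.array([fractions[c] for c in labels], dtype=float)
    if probs.sum() <= 0:
        raise ConfigurationError("class fractions must sum to a positive value")
    probs = probs / probs.sum()
    genes = sorted({g.gene for g in library.guides if not g.is_negative_control})
    gene_class = {gn: labels[int(i)] for gn, i in zip(genes, rng.choice(len(labels), size=len(genes), p=probs))}
    return {
        g.guide_id: ("neutral" if g.is_negative_control else gene_class[g.gene])
        for g in library.guides
    }


def generate_truth(
    library: GuideLibrary,
    params: TruthParams | None = None,
    seed: int | np.random.Generator = 0,
    class_assignment: dict | None = None,
) -> TruthModel:
    """Draw per-guide truth parameters given a class assignment.

    ``class_assignment`` may map gene names (or individual guide_ids) to
    class labels; if omitted, classes are drawn per gene from
    ``params.class_fractions``.  Negative controls are always neutral with a
    flat zero surface.
    """
    params = params or TruthParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    unknown = set(params.class_fractions) - set(CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown classes: {sorted(unknown)}")
    classes = _assign_classes(library, params.class_fractions, rng, class_assignment)

    rows = []
    u = rng.uniform
    for g in library.guides:
        cls = classes[g.guide_id]
        gamma = 0.0
        beta0 = 0.0
        amp = 0.0
        ec50 = params.ec50_translation
        tau = u(*params.onset_fast_h)
        alpha = u(*params.adaptation_range)
        if cls == "translation":
            gamma = u(*params.gamma_range_translation)
            beta0 = -params.growth_isr_coupling * gamma
            amp = u(*params.amplitude_range)
        elif cls == "pcl5_feedback":
            beta0 = u(*params.basal_range_pcl5)
            amp = u(*params.amplitude_range_pcl5)
            tau = 0.5 * u(*params.onset_fast_h)
            alpha = 0.0
        elif cls == "ribi":
            gamma = u(*params.gamma_range_ribi)
            beta0 = u(*params.basal_range_ribi)
            amp = u(*params.amplitude_range)
            ec50 = params.ec50_translation * params.ribi_ec50_shift
            tau = u(*params.onset_ribi_h)
        elif cls == "proteasome":
            gamma = u(*params.gamma_range_proteasome)
            beta0 = u(*params.basal_range_proteasome)
            amp = u(*params.amplitude_range)
            ec50 = params.ec50_translation * params.proteasome_ec50_shift
            tau = u(*params.onset_proteasome_h)
            alpha = u(*params.adaptation_range_proteasome)
        elif cls != "neutral":
            raise ConfigurationError(f"unknown class {cls!r}")
        if cls == "neutral":
            alpha = 0.0
        rows.append(
            {
                "guide_id": g.guide_id,
                "class_label": cls,
                "growth_effect": gamma,
                "basal_isr": beta0,
                "amplitude": amp,
                "ec50": ec50,
                "hill": params.hill,
                "onset_h": tau,
                "adaptation": alpha,
            }
        )
    df = pd.DataFrame(rows).set_index("guide_id", drop=False)
    return TruthModel(guides=df)
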