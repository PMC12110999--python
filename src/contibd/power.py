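"""Monte-Carlo likelihood-ratio distributions and classification power.

Genomes are simulated under a generating hypothesis, each is scored with
the exact segment likelihood ratio of two hypotheses, and the resulting
log10 LR samples are summarized into rates of misleading evidence, median
log10 LRs and the accuracy of the ``LR >= 1`` classifier under equal
priors.  Ties (``LR == 1`` exactly) are assigned to H1 and also reported
separately, since identical-law pairs carry a point mass there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .genmap import GeneticMap
from .likelihood import Hypothesis, likelihood_ratio
from .simulate import simulate_ibd
from .statespace import DEFAULT_EPSILON

__all__ = [
    "LRSampleSet",
    "PowerSummary",
    "sample_lr_distribution",
    "summarize_power",
    "pairwise_power",
    "one_vs_rest_study",
]

logger = logging.getLogger("contibd")


@dataclass(frozen=True)
class LRSampleSet:
    """log10 LR draws for one generating hypothesis."""

    truth_label: str
    h1_label: str
    h2_label: str
    log10_lr: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "log10_lr", np.asarray(self.log10_lr, dtype=float)
        )

    @property
    def reps(self) -> int:
        return int(self.log10_lr.size)


def sample_lr_distribution(
    h_true: Hypothesis | str,
    h1: Hypothesis | str,
    h2: Hypothesis | str,
    gmap: GeneticMap,
    reps: int,
    seed: int,
    epsilon: float = DEFAULT_EPSILON,
) -> LRSampleSet:
    """Draw ``reps`` log10 LR samples with genomes generated under ``h_true``.

    A composite ``h_true`` picks its generating component uniformly by
    weight for each replicate.  Fully reproducible under ``seed``: replicate
    ``r`` simulates with substream ``(seed, r)``.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    h_true = Hypothesis.of(h_true)
    h1 = Hypothesis.of(h1)
    h2 = Hypothesis.of(h2)
    picker = np.random.default_rng([seed, 2**31])
    choices = picker.choice(
        len(h_true.components), size=reps, p=np.asarray(h_true.weights)
    )
    out = np.empty(reps)
    for r in range(reps):
        ped = h_true.components[choices[r]]
        segs = simulate_ibd(ped, gmap, seed=[seed, r])
        out[r] = likelihood_ratio(segs, h1, h2, epsilon).log10_lr
        if (r + 1) % 500 == 0:
            logger.info(
                "sample_lr_distribution[%s vs %s | %s true]: %d/%d",
                h1.label, h2.label, h_true.label, r + 1, reps,
            )
    return LRSampleSet(
        truth_label=h_true.label,
        h1_label=h1.label,
        h2_label=h2.label,
        log10_lr=out,
        seed=seed,
    )


@dataclass(frozen=True)
class PowerSummary:
    """Classification power of the ``LR >= 1`` rule under equal priors."""

    h1_label: str
    h2_label: str
    reps_h1: int
    reps_h2: int
    pr_gt1_h1: float
    pr_lt1_h1: float
    pr_eq1_h1: float
    pr_gt1_h2: float
    pr_lt1_h2: float
    pr_eq1_h2: float
    median_log10_lr_h1: float
    median_log10_lr_h2: float
    accuracy: float
    se_pr_gt1_h1: float
    se_pr_lt1_h2: float
    se_accuracy: float


def _rate_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))


def summarize_power(s1: LRSampleSet, s2: LRSampleSet) -> PowerSummary:
    """Summarize H1-true and H2-true LR samples for one hypothesis pair.

    ``accuracy = (Pr(LR >= 1 | H1) + Pr(LR < 1 | H2)) / 2`` — ties count as
    an assignment to H1.  Standard errors are binomial.
    """
    if (s1.h1_label, s1.h2_label) != (s2.h1_label, s2.h2_label):
        raise ValidationError(
            "sample sets summarize different hypothesis pairs: "
            f"({s1.h1_label}, {s1.h2_label}) vs ({s2.h1_label}, {s2.h2_label})"
        )
    a1, a2 = s1.log10_lr, s2.log10_lr
    gt1_h1 = float(np.mean(a1 > 0))
    lt1_h1 = float(np.mean(a1 < 0))
    gt1_h2 = float(np.mean(a2 > 0))
    lt1_h2 = float(np.mean(a2 < 0))
    correct_h1 = float(np.mean(a1 >= 0))  # ties to H1
    acc = 0.5 * (correct_h1 + lt1_h2)
    se_acc = 0.5 * np.hypot(
        _rate_se(correct_h1, s1.reps), _rate_se(lt1_h2, s2.reps)
    )
    return PowerSummary(
        h1_label=s1.h1_label,
        h2_label=s1.h2_label,
        reps_h1=s1.reps,
        reps_h2=s2.reps,
        pr_gt1_h1=gt1_h1,
        pr_lt1_h1=lt1_h1,
        pr_eq1_h1=float(np.mean(a1 == 0)),
        pr_gt1_h2=gt1_h2,
        pr_lt1_h2=lt1_h2,
        pr_eq1_h2=float(np.mean(a2 == 0)),
        median_log10_lr_h1=float(np.median(a1)),
        median_log10_lr_h2=float(np.median(a2)),
        accuracy=float(acc),
        se_pr_gt1_h1=_rate_se(gt1_h1, s1.reps),
        se_pr_lt1_h2=_rate_se(lt1_h2, s2.reps),
        se_accuracy=float(se_acc),
    )


def pairwise_power(
    h1: Hypothesis | str,
    h2: Hypothesis | str,
    gmap: GeneticMap,
    reps: int,
    seed: int,
    epsilon: float = DEFAULT_EPSILON,
) -> PowerSummary:
    """Convenience: sample both truth sides and summarize.

    H1-true draws use substreams of ``seed``; H2-true draws use
    ``seed + 1``.
    """
    s1 = sample_lr_distribution(h1, h1, h2, gmap, reps, seed, epsilon)
    s2 = sample_lr_distribution(h2, h1, h2, gmap, reps, seed + 1, epsilon)
    return summarize_power(s1, s2)


def one_vs_rest_study(
    relationships,
    gmap: GeneticMap,
    reps: int,
    seed: int,
    epsilon: float = DEFAULT_EPSILON,
) -> list[PowerSummary]:
    """One-vs-rest power for each relationship in a set.

    For relationship ``R`` the alternative is the equal-weight composite of
    the other set members; H2-true replicates draw their generating member
    uniformly from the complement.
    """
    hyps = [Hypothesis.of(r) for r in relationships]
    if len(hyps) < 2:
        raise ValidationError("one_vs_rest_study needs at least 2 relationships")
    for h in hyps:
        if len(h.components) != 1:
            raise ValidationError("set members must be single relationships")
    out = []
    for i, h1 in enumerate(hyps):
        rest = [h for j, h in enumerate(hyps) if j != i]
        h2 = Hypothesis.of([h.components[0] for h in rest])
        out.append(
            pairwise_power(h1, h2, gmap, reps, seed + 1000 * i, epsilon)
        )
    return out
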