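"""Verification experiments on synthetic data.

Self-contained recovery and calibration runs used by the test suite and the
reproduction script: noise-free and moderate-noise end-to-end studies with
ground-truth comparison, type-I-error calibration of the circular tests,
a brute-force check of the Benjamini-Hochberg step-up, and the angular-shift
sensitivity experiment.

A note on reference angles: the laterality mirror folds a bilateral angular
law about the vertical axis, so the mean of the mirrored distribution is
not the right-side component's mu.  Reference means per cell class are
therefore computed by drawing directly from the configured generative
mixture (weighted by expected population counts) and folding, and the
pipeline's pooled detected means are compared against those.
"""

from __future__ import annotations

import numpy as np

from . import circstats, linstats
from .detect import MARKERS
from .geometry import mirror_left_to_right
from .pipeline import CELL_CLASSES, StudyConfig, evaluate_recovery
from .synthdata import SectionConfig, sample_angles

#: Study-scale section settings for the two recovery regimes.  SNR is the
#: projected cell amplitude (z-weight 0.5 x 20000) over the noise sd.
NOISE_FREE = dict(enforce_separation=True, noise_sd=0.0,
                  gradient_amplitude=0.0)
MODERATE_NOISE = dict(enforce_separation=True, noise_sd=2000.0,
                      gradient_amplitude=1000.0)  # SNR ~ 5


def study_config(seed: int, noise: bool = False, **overrides) -> StudyConfig:
    section = SectionConfig(**(MODERATE_NOISE if noise else NOISE_FREE))
    return StudyConfig(section=section, seed=seed, **overrides)


def _class_component_mix(populations) -> dict:
    """Per cell class: [(angular components, expected count weight), ...]."""

    def pops_with(marker):
        out = []
        for spec in populations:
            if marker in spec.markers:
                out.append((spec.angular, float(spec.count)))
            elif marker in spec.coexpression:
                out.append((spec.angular,
                            float(round(spec.coexpression[marker]
                                        * spec.count))))
        return out

    def pops_with_both(a, b):
        out = []
        for spec in populations:
            w = float(spec.count)
            for m in (a, b):
                if m in spec.markers:
                    continue
                if m in spec.coexpression:
                    w *= spec.coexpression[m]
                else:
                    w = 0.0
            if w > 0:
                out.append((spec.angular, round(w)))
        return out

    mix = {m: pops_with(m) for m in MARKERS}
    mix["ChAT_interneuron"] = [
        (spec.angular, float(spec.count)) for spec in populations
        if "ChAT" in spec.markers and spec.diameter_um[1] <= 25.0]
    mix["ChAT_motor_neuron"] = [
        (spec.angular, float(spec.count)) for spec in populations
        if "ChAT" in spec.markers and spec.diameter_um[0] >= 25.0]
    mix["ChAT+GAD67"] = pops_with_both("ChAT", "GAD67")
    mix["Parvalbumin+GAD67"] = pops_with_both("Parvalbumin", "GAD67")
    mix["Parvalbumin+Calbindin"] = pops_with_both("Parvalbumin", "Calbindin")
    return mix


def class_reference_mirrored_means(populations, seed: int = 0,
                                   n: int = 200_000) -> dict:
    """Mean of the generative mirrored angular law per cell class."""
    rng = np.random.default_rng(seed)
    refs = {}
    for cls, parts in _class_component_mix(populations).items():
        weights = np.array([w for _, w in parts])
        draws = []
        for (comps, w), k in zip(parts,
                                 np.round(n * weights / weights.sum())):
            if k > 0:
                draws.append(sample_angles(comps, int(k), rng))
        mirrored = mirror_left_to_right(np.concatenate(draws))
        refs[cls] = circstats.circular_mean(mirrored)
    return refs


def recovery_report(bundle) -> dict:
    """Count/centroid/angle recovery of one synthetic study run.

    The angular check compares, per cell class, the pooled mirrored mean of
    the detected cells with the pooled mirrored mean of the ground-truth
    cells — the angles the generator actually realised after placement —
    so it isolates distortion introduced by the imaging chain.
    """
    from .pipeline import class_selector, truth_class_selector

    rec = evaluate_recovery(bundle.cells, bundle.truth)
    report = {
        "detected": rec["detected"],
        "truth": rec["truth"],
        "count_pct_error": {
            cls: 100.0 * (rec["detected"][cls] - rec["truth"][cls])
            / max(rec["truth"][cls], 1) for cls in CELL_CLASSES},
        "centroid_error_mean_px": rec["centroid_error_mean_px"],
        "centroid_error_max_px": rec["centroid_error_max_px"],
        "n_matched": rec["n_matched"],
    }
    diffs = {}
    for cls in CELL_CLASSES:
        det = bundle.cells.loc[class_selector(bundle.cells, cls),
                               "mirrored_angle_deg"].to_numpy()
        tru = mirror_left_to_right(
            bundle.truth.loc[truth_class_selector(bundle.truth, cls),
                             "angle_deg"].to_numpy())
        diff = circstats.circular_mean(det) - circstats.circular_mean(tru)
        diffs[cls] = float((diff + 180.0) % 360.0 - 180.0)
    report["mirrored_mean_error_deg"] = diffs
    return report


def cmtest_type1_rate(n_reps: int = 1000, n_per_group: int = 50,
                      k_groups: int = 4, alpha: float = 0.05,
                      seed: int = 0) -> float:
    """Rejection rate of the common-median test under a uniform null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        groups = [rng.uniform(0, 360, n_per_group) for _ in range(k_groups)]
        try:
            res = circstats.common_median_test(groups)
        except circstats.DegeneratePartitionError:
            continue
        rejections += res.p_value < alpha
    return rejections / n_reps


def kuiper_type1_rate(n_reps: int = 1000, n_per_group: int = 50,
                      n_perm: int = 1000, alpha: float = 0.05,
                      seed: int = 0) -> float:
    """Rejection rate of the permutation Kuiper test under a uniform null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.uniform(0, 360, n_per_group)
        b = rng.uniform(0, 360, n_per_group)
        res = circstats.kuiper_two_sample(a, b, n_perm=n_perm, seed=rng)
        rejections += res.p_value < alpha
    return rejections / n_reps


def bh_step_up_oracle(pvals) -> np.ndarray:
    """Plain-loop Benjamini-Hochberg step-up, independent of the library."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def bh_max_abs_difference(base_pvals=None) -> float:
    """Max |q - oracle q| over all 2^8 sign patterns of an 8-p fixture.

    Each pattern replaces p_i by either its value or 1 - its value.
    """
    if base_pvals is None:
        base_pvals = np.array([0.001, 0.008, 0.02, 0.04, 0.049, 0.2,
                               0.45, 0.9])
    base = np.asarray(base_pvals, dtype=float)
    worst = 0.0
    for pattern in range(2 ** base.size):
        bits = (pattern >> np.arange(base.size)) & 1
        p = np.where(bits, 1.0 - base, base)
        diff = np.abs(circstats.bh_adjust(p) - bh_step_up_oracle(p)).max()
        worst = max(worst, float(diff))
    return worst


def shift_sensitivity(
    n_reps: int = 20,
    shift_deg: float = 7.5,
    n_per_group: int = 2000,
    kappa: float = 2.4,
    mu_deg: float = 5.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detectability of a small angular shift in one genotype's population.

    Per replicate, four genotype samples of pooled mirrored angles are drawn
    from the generative bilateral law (kappa matching the study's observed
    circular variances); one genotype's law is shifted by ``shift_deg``.
    Detection requires BH-adjusted Kuiper q < alpha for all three pairs
    involving the shifted genotype (after a significant omnibus
    common-median test).  Matched null count and distance data are analysed
    alongside, to confirm the shift leaves those layers non-significant.
    """
    from .pipeline import shift_components
    from .synthdata import VonMisesComponent

    base_comps = (VonMisesComponent(mu_deg, kappa, 0.5),
                  VonMisesComponent((180.0 - mu_deg) % 360.0, kappa, 0.5))
    shifted_comps = shift_components(base_comps, shift_deg)
    rng = np.random.default_rng(seed)
    detected = 0
    counts_nonsig = 0
    dist_nonsig = 0
    for _ in range(n_reps):
        groups = {}
        for g in range(4):
            comps = shifted_comps if g == 3 else base_comps
            raw = sample_angles(comps, n_per_group, rng)
            groups[g] = mirror_left_to_right(raw)
        omni = circstats.common_median_test(list(groups.values()))
        pvals, pairs = [], []
        for i in range(4):
            for j in range(i + 1, 4):
                res = circstats.kuiper_two_sample(groups[i], groups[j],
                                                  n_perm=n_perm, seed=rng)
                pvals.append(res.p_value)
                pairs.append((i, j))
        q = circstats.bh_adjust(pvals)
        shifted_pairs_sig = all(
            qv < alpha for qv, (i, j) in zip(q, pairs) if 3 in (i, j))
        detected += (omni.p_value < alpha) and shifted_pairs_sig

        # matched null layers: Poisson section counts, common distance law
        totals = rng.poisson(8 * 65, size=(4, 3))
        _, p_count = linstats.one_way_anova(list(totals.astype(float)))
        counts_nonsig += p_count >= alpha
        values, genos, anims = [], [], []
        for g in range(4):
            for a in range(3):
                d = rng.beta(2.0, 2.0, 150) + rng.normal(0.0, 0.02)
                values.append(d)
                genos.extend([g] * d.size)
                anims.extend([f"{g}:{a}"] * d.size)
        _, p_dist = linstats.nested_anova(np.concatenate(values), genos,
                                          anims)
        dist_nonsig += p_dist >= alpha
    return {
        "detection_rate": detected / n_reps,
        "counts_nonsignificant_rate": counts_nonsig / n_reps,
        "distances_nonsignificant_rate": dist_nonsig / n_reps,
    }
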