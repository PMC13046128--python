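"""Linear statistics on cell counts and normalised distances.

Counts (one value per animal) are compared across genotypes by an ordinary
one-way ANOVA.  Per-cell normalised distances are compared by a nested
one-way ANOVA with animals nested in genotype: the genotype mean square is
tested against the animal-within-genotype mean square, so animals - not
cells - are the units of replication.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and upper-tail p across k groups.

    F = MS_between / MS_within with (k - 1, N - k) degrees of freedom.
    Raises when the pooled within-group variance is zero.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    n = np.array([s.size for s in samples])
    big_n = int(n.sum())
    grand = np.concatenate(samples).mean()
    means = np.array([s.mean() for s in samples])
    ss_between = float((n * (means - grand) ** 2).sum())
    ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    if ss_within <= 0:
        raise ValueError("zero within-group variance; F undefined")
    df_b, df_w = k - 1, big_n - k
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def nested_anova(values, genotype, animal) -> tuple[float, float]:
    """Nested one-way ANOVA: genotype tested against animal-within-genotype.

    Sequential (genotype-first) sums of squares for the unbalanced case:

        SS_genotype = sum_i N_i (ybar_i - ybar)^2
        SS_animal   = sum_ij n_ij (ybar_ij - ybar_i)^2

    F = MS_genotype / MS_animal with (k - 1, sum_i (a_i - 1)) degrees of
    freedom, where a_i is the number of animals in genotype i.  Animal means
    are weighted by their cell counts.  With one value per animal this
    reduces exactly to a one-way ANOVA on the animal means.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "genotype": np.asarray(genotype),
        "animal": np.asarray(animal),
    })
    if df["genotype"].nunique() < 2:
        raise ValueError("need at least two genotypes")
    animals_per = df.groupby("genotype")["animal"].nunique()
    if (animals_per < 2).any():
        raise ValueError("every genotype needs at least two animals")

    grand = df["value"].mean()
    geno = df.groupby("genotype")["value"].agg(["mean", "count"])
    ss_geno = float((geno["count"] * (geno["mean"] - grand) ** 2).sum())

    anim = df.groupby(["genotype", "animal"])["value"].agg(["mean", "count"])
    geno_mean = geno["mean"].reindex(anim.index.get_level_values(0)).to_numpy()
    ss_anim = float((anim["count"].to_numpy()
                     * (anim["mean"].to_numpy() - geno_mean) ** 2).sum())

    k = geno.shape[0]
    df_geno = k - 1
    df_anim = int((animals_per - 1).sum())
    if ss_anim <= 0:
        if ss_geno <= 1e-12:
            return 0.0, 1.0  # all animal means coincide
        raise ValueError("zero animal-to-animal variance; F undefined")
    f = (ss_geno / df_geno) / (ss_anim / df_anim)
    p = float(stats.f.sf(f, df_geno, df_anim))
    return float(f), p


def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk normality screen (delegated to the standard routine)."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)
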