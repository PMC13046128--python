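"""End-to-end orchestration: sections -> cells -> group statistics.

A study is 4 genotypes x 3 animals x 8 sections (two per lumbar level
L3-L6).  Each section is processed blind to its metadata: the imaging chain
and particle extraction run per channel before genotype labels are joined,
then cells are pooled per cell class and genotype for the statistics layer
(one-way ANOVA on counts, nested ANOVA on normalised distances, circular
common-median test with Kuiper post hocs and Benjamini-Hochberg FDR on
mirrored angles).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import circstats, linstats
from .detect import (DEFAULT_OVERLAP_CUTOFF, MARKERS, SIZE_WINDOWS,
                     classify_chat_size, double_positives, find_particles)
from .geometry import annotate_cells
from .imgproc import SectionGeometry, segment_channel
from .synthdata import (RadialBoundary, SectionConfig, VonMisesComponent,
                        _section_count, make_section_geometry,
                        render_section, sample_population)

#: Analysis cell classes, as counted and tested per genotype.
CELL_CLASSES = (
    "ChAT", "ChAT_interneuron", "ChAT_motor_neuron",
    "GAD67", "Calbindin", "Parvalbumin",
    "ChAT+GAD67", "Parvalbumin+GAD67", "Parvalbumin+Calbindin",
)

#: (anchor marker, other marker) pairs for colocalisation, anchored on the
#: first-listed marker's particles.
COLOC_PAIRS = (
    ("ChAT", "GAD67"),
    ("Parvalbumin", "GAD67"),
    ("Parvalbumin", "Calbindin"),
)

GENOTYPES = ("+/+", "-/+", "+/Loa", "-/Loa")
LUMBAR_LEVELS = ("L3", "L4", "L5", "L6")


@dataclass
class AnalysisParams:
    """Per-section processing settings."""

    rolling_ball_radius_px: int = 20
    coloc_cutoff: float = DEFAULT_OVERLAP_CUTOFF
    normalisation_variant: str = "radial_fraction"

    def __post_init__(self):
        if not 0.0 <= self.coloc_cutoff <= 1.0:
            raise ValueError("colocalisation cutoff must lie in [0, 1]")


@dataclass
class StudyConfig:
    """A full synthetic study: design, section template and statistics."""

    genotypes: tuple[str, ...] = GENOTYPES
    animals_per_genotype: int = 3
    sections_per_animal: int = 8
    section: SectionConfig = field(default_factory=SectionConfig)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    alpha: float = 0.05
    n_perm: int = 2000
    seed: int = 0
    #: genotype -> {population name -> angular shift in degrees}, applied to
    #: the mirrored distribution (left-side modes move opposite so the
    #: mirrored angles shift by the stated amount).
    angle_shift: dict = field(default_factory=dict)


def shift_components(components, delta_deg: float):
    """Shift a bilateral von Mises mixture so mirrored angles move by delta.

    Components whose mean lies on the right half-circle move by +delta;
    left-side components move by -delta, so that after the laterality mirror
    every mode lands delta degrees further along.
    """
    out = []
    for c in components:
        mu = c.mu_deg % 360.0
        right = mu <= 90.0 or mu >= 270.0
        d = delta_deg if right else -delta_deg
        out.append(VonMisesComponent((mu + d) % 360.0, c.kappa, c.weight))
    return tuple(out)


def analyze_section(stacks: dict, geometry: SectionGeometry,
                    params: AnalysisParams | None = None) -> pd.DataFrame:
    """Process one section's four channels into a per-cell table.

    Runs the imaging chain and particle extraction per marker, the ChAT
    size split, anchored colocalisation for the three marker pairs, and the
    polar/mirror/normalisation geometry.  Returns one row per detected cell
    with marker, centroid, area, overlap fractions and polar fields.
    """
    params = params or AnalysisParams()
    pixel_size = next(iter(stacks.values())).pixel_size
    binaries = {m: segment_channel(stacks[m], geometry,
                                   params.rolling_ball_radius_px)
                for m in MARKERS}
    cells_by_marker = {
        m: find_particles(binaries[m], pixel_size, SIZE_WINDOWS[m])
        for m in MARKERS
    }
    classify_chat_size(cells_by_marker["ChAT"])
    for anchor, other in COLOC_PAIRS:
        double_positives(cells_by_marker[anchor], binaries[other], other,
                         params.coloc_cutoff)
    rows = []
    for marker, cells in cells_by_marker.items():
        annotate_cells(cells, geometry, pixel_size,
                       params.normalisation_variant)
        for c in cells:
            rows.append({
                "marker": marker,
                "x_px": c.centroid[0],
                "y_px": c.centroid[1],
                "area_um2": c.area_um2,
                "size_class": c.size_class,
                "angle_deg": c.angle_deg,
                "mirrored_angle_deg": c.mirrored_angle_deg,
                "distance_um": c.distance_um,
                "norm_distance": c.norm_distance,
                "ovl_GAD67": c.coexpression.get("GAD67", np.nan),
                "ovl_Calbindin": c.coexpression.get("Calbindin", np.nan),
            })
    return pd.DataFrame(rows)


def class_selector(cells: pd.DataFrame, cell_class: str,
                   cutoff: float = DEFAULT_OVERLAP_CUTOFF) -> pd.Series:
    """Boolean selector of one analysis class in a per-cell table."""
    m = cells["marker"]
    if cell_class == "ChAT_interneuron":
        return (m == "ChAT") & (cells["size_class"] == "interneuron")
    if cell_class == "ChAT_motor_neuron":
        return (m == "ChAT") & (cells["size_class"] == "motor_neuron")
    if cell_class == "ChAT+GAD67":
        return (m == "ChAT") & (cells["ovl_GAD67"] >= cutoff)
    if cell_class == "Parvalbumin+GAD67":
        return (m == "Parvalbumin") & (cells["ovl_GAD67"] >= cutoff)
    if cell_class == "Parvalbumin+Calbindin":
        return (m == "Parvalbumin") & (cells["ovl_Calbindin"] >= cutoff)
    if cell_class in MARKERS:
        return m == cell_class
    raise ValueError(f"unknown cell class {cell_class!r}")


def rose_histogram(angles_deg, n_bins: int = 36) -> pd.DataFrame:
    """Percentage of cells per angular bin (equal-width bins over [0, 360)).

    Bar lengths of a rose diagram; the percentages sum to 100.
    """
    a = np.asarray(angles_deg, dtype=float) % 360.0
    if a.size == 0:
        raise ValueError("empty angle sample")
    if n_bins < 4:
        raise ValueError("need at least 4 bins")
    counts, edges = np.histogram(a, bins=n_bins, range=(0.0, 360.0))
    return pd.DataFrame({
        "bin_start_deg": edges[:-1],
        "bin_end_deg": edges[1:],
        "percent": 100.0 * counts / a.size,
    })


def summarize_counts(cells: pd.DataFrame,
                     manifest: pd.DataFrame,
                     cutoff: float = DEFAULT_OVERLAP_CUTOFF) -> pd.DataFrame:
    """Per animal x class counts, summed over the animal's sections.

    ``manifest`` must list every (genotype, animal, section_id) so that
    empty classes are carried as zero counts rather than dropped.
    """
    animals = manifest[["genotype", "animal"]].drop_duplicates()
    if animals.empty:
        raise ValueError("empty manifest")
    per_animal_sections = manifest.groupby("animal")["section_id"].nunique()
    if (per_animal_sections < 1).any():
        raise ValueError("animal with zero sections")
    rows = []
    for _, rec in animals.iterrows():
        sel_animal = cells["animal"] == rec["animal"]
        for cls in CELL_CLASSES:
            n = int((class_selector(cells, cls, cutoff) & sel_animal).sum())
            rows.append({"genotype": rec["genotype"], "animal": rec["animal"],
                         "cell_class": cls, "count": n})
    return pd.DataFrame(rows)


@dataclass
class ResultsBundle:
    """All tables produced by one study run."""

    cells: pd.DataFrame
    manifest: pd.DataFrame
    count_table: pd.DataFrame
    count_summary: pd.DataFrame
    count_stats: pd.DataFrame
    distance_stats: pd.DataFrame
    circular_summary: pd.DataFrame
    circular_tests: pd.DataFrame
    pairwise_tests: pd.DataFrame
    rose_tables: pd.DataFrame
    truth: pd.DataFrame | None = None
    run_log: dict = field(default_factory=dict)

    def _tables(self):
        return {
            "cells": self.cells, "manifest": self.manifest,
            "count_table": self.count_table,
            "count_summary": self.count_summary,
            "count_stats": self.count_stats,
            "distance_stats": self.distance_stats,
            "circular_summary": self.circular_summary,
            "circular_tests": self.circular_tests,
            "pairwise_tests": self.pairwise_tests,
            "rose_tables": self.rose_tables,
        }

    def bundle_hash(self) -> str:
        """SHA-256 over all result tables' CSV bytes (reproducibility check)."""
        h = hashlib.sha256()
        for name, df in sorted(self._tables().items()):
            h.update(name.encode())
            h.update(df.to_csv(index=False, float_format="%.10g").encode())
        return h.hexdigest()

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self._tables().items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(outdir / "truth.csv", index=False)
        log = dict(self.run_log)
        log["bundle_hash"] = self.bundle_hash()
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)


def _study_statistics(cells: pd.DataFrame, manifest: pd.DataFrame,
                      config: StudyConfig,
                      stat_rng: np.random.Generator) -> dict:
    """Pooled statistics layer shared by synthetic and file-based runs."""
    cutoff = config.params.coloc_cutoff
    count_table = summarize_counts(cells, manifest, cutoff)
    count_summary = (count_table.groupby(["genotype", "cell_class"])["count"]
                     .agg(["mean", "std"]).reset_index())

    count_rows, dist_rows = [], []
    circ_sum_rows, circ_test_rows, pair_rows, rose_rows = [], [], [], []
    for cls in CELL_CLASSES:
        # counts: one-way ANOVA on animal totals
        by_cls = count_table[count_table["cell_class"] == cls]
        grp = [by_cls.loc[by_cls["genotype"] == g, "count"].to_numpy()
               for g in config.genotypes]
        try:
            f, p = linstats.one_way_anova(grp)
        except ValueError:
            f, p = np.nan, np.nan
        count_rows.append({"cell_class": cls, "F": f, "p": p})

        sel = class_selector(cells, cls, cutoff)
        sub = cells[sel]
        # distances: nested ANOVA, animals within genotype
        try:
            f, p = linstats.nested_anova(sub["norm_distance"],
                                         sub["genotype"], sub["animal"])
        except ValueError:
            f, p = np.nan, np.nan
        dist_rows.append({"cell_class": cls, "F": f, "p": p})

        # circular layer: pooled mirrored angles per genotype
        groups = {g: sub.loc[sub["genotype"] == g, "mirrored_angle_deg"]
                  .to_numpy() for g in config.genotypes}
        for g, a in groups.items():
            row = {"cell_class": cls, "genotype": g, "n": a.size,
                   "circ_mean_deg": np.nan, "circ_variance": np.nan,
                   "ci_low_deg": np.nan, "ci_high_deg": np.nan}
            if a.size:
                try:
                    row["circ_mean_deg"] = circstats.circular_mean(a)
                    row["circ_variance"] = circstats.circular_variance(a)
                    mean, lo, hi = circstats.mean_angle_ci(a)
                    row["ci_low_deg"], row["ci_high_deg"] = lo, hi
                except ValueError:
                    pass
            circ_sum_rows.append(row)
            if a.size:
                rh = rose_histogram(a)
                rh.insert(0, "cell_class", cls)
                rh.insert(1, "genotype", g)
                rose_rows.append(rh)

        try:
            omni = circstats.common_median_test(
                list(groups.values()), labels=list(groups))
            circ_test_rows.append({"cell_class": cls, "test": omni.label,
                                   "statistic": omni.statistic, "df": omni.df,
                                   "p": omni.p_value})
            run_posthoc = omni.p_value < config.alpha
        except ValueError:
            circ_test_rows.append({"cell_class": cls,
                                   "test": "common_median_test",
                                   "statistic": np.nan, "df": np.nan,
                                   "p": np.nan})
            run_posthoc = False
        # no post hoc tests after a non-significant main effect
        if run_posthoc:
            names = list(groups)
            pvals, prows = [], []
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    res = circstats.kuiper_two_sample(
                        groups[names[i]], groups[names[j]],
                        n_perm=config.n_perm, seed=stat_rng)
                    pvals.append(res.p_value)
                    prows.append({"cell_class": cls, "group_a": names[i],
                                  "group_b": names[j], "V": res.statistic,
                                  "p": res.p_value})
            for row, q in zip(prows, circstats.bh_adjust(pvals)):
                row["q"] = q
                pair_rows.append(row)

    empty_pair = pd.DataFrame(
        columns=["cell_class", "group_a", "group_b", "V", "p", "q"])
    return {
        "count_table": count_table,
        "count_summary": count_summary,
        "count_stats": pd.DataFrame(count_rows),
        "distance_stats": pd.DataFrame(dist_rows),
        "circular_summary": pd.DataFrame(circ_sum_rows),
        "circular_tests": pd.DataFrame(circ_test_rows),
        "pairwise_tests": pd.DataFrame(pair_rows) if pair_rows else empty_pair,
        "rose_tables": pd.concat(rose_rows, ignore_index=True),
    }


def run_synthetic_study(config: StudyConfig) -> ResultsBundle:
    """Generate, process and statistically analyse a full synthetic study.

    Sections are generated and analysed one at a time (streaming, so only
    tables persist); all randomness descends from ``config.seed``, and a
    re-run with the same config reproduces byte-identical tables.
    """
    ss = np.random.SeedSequence(config.seed)
    n_sections = (len(config.genotypes) * config.animals_per_genotype
                  * config.sections_per_animal)
    children = ss.spawn(n_sections + 1)
    stat_rng = np.random.default_rng(children[-1])

    geometry = make_section_geometry(config.section)
    boundary = RadialBoundary(geometry.gray_mask, geometry.canal_centroid,
                              geometry.dorsal_up)
    from scipy import ndimage as ndi
    depth_map = ndi.distance_transform_edt(geometry.gray_mask)

    pops_by_genotype = {}
    for g in config.genotypes:
        shifts = config.angle_shift.get(g, {})
        pops = []
        for spec in config.section.populations:
            if spec.name in shifts:
                spec = replace(spec, angular=shift_components(
                    spec.angular, shifts[spec.name]))
            pops.append(spec)
        pops_by_genotype[g] = tuple(pops)

    cell_frames, truth_frames, manifest_rows = [], [], []
    idx = 0
    for g in config.genotypes:
        for a in range(config.animals_per_genotype):
            animal = f"{g}_m{a + 1}"
            for s in range(config.sections_per_animal):
                level = LUMBAR_LEVELS[(s // 2) % len(LUMBAR_LEVELS)]
                section_id = f"{animal}_s{s + 1}"
                rng = np.random.default_rng(children[idx])
                idx += 1
                placed: list = []
                cells = []
                for spec in pops_by_genotype[g]:
                    if config.section.poisson_counts:
                        spec = replace(
                            spec, count=_section_count(spec.count, rng))
                    cells.extend(sample_population(
                        spec, geometry, config.section.pixel_size, rng,
                        placed=placed,
                        enforce_separation=config.section.enforce_separation,
                        separation_um=config.section.separation_um,
                        retry_budget=config.section.retry_budget,
                        start_id=len(cells), boundary=boundary,
                        depth_map=depth_map))
                stacks, truth = render_section(cells, geometry,
                                               config.section, rng)
                detected = analyze_section(stacks, geometry, config.params)
                for df in (detected, truth):
                    df["section_id"] = section_id
                    df["animal"] = animal
                    df["genotype"] = g
                    df["lumbar_level"] = level
                cell_frames.append(detected)
                truth_frames.append(truth)
                manifest_rows.append({"section_id": section_id,
                                      "animal": animal, "genotype": g,
                                      "lumbar_level": level})

    cells = pd.concat(cell_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)
    tables = _study_statistics(cells, manifest, config, stat_rng)
    run_log = {"seed": config.seed, "n_sections": n_sections,
               "alpha": config.alpha, "n_perm": config.n_perm,
               "genotypes": list(config.genotypes)}
    return ResultsBundle(cells=cells, manifest=manifest, truth=truth,
                         run_log=run_log, **tables)


def run_study(manifest: pd.DataFrame, load_section, config: StudyConfig
              ) -> ResultsBundle:
    """Process a study from a manifest of stored sections.

    ``manifest`` needs columns section_id, animal, genotype, lumbar_level
    plus whatever ``load_section(row) -> (stacks, geometry)`` requires
    (typically a directory column).  Sections are processed before their
    metadata is joined, so the imaging layer is blind to genotype.
    """
    stat_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0])
    per_animal = manifest.groupby("animal")["section_id"].nunique()
    expected = config.sections_per_animal
    for animal, n in per_animal.items():
        if n != expected:
            import warnings
            warnings.warn(f"animal {animal}: {n} sections, expected {expected}")
    frames = []
    for _, row in manifest.iterrows():
        stacks, geometry = load_section(row)
        detected = analyze_section(stacks, geometry, config.params)
        for key in ("section_id", "animal", "genotype", "lumbar_level"):
            detected[key] = row[key]
        frames.append(detected)
    cells = pd.concat(frames, ignore_index=True)
    tables = _study_statistics(cells, manifest, config, stat_rng)
    run_log = {"seed": config.seed, "n_sections": len(manifest)}
    return ResultsBundle(cells=cells, manifest=manifest, run_log=run_log,
                         **tables)


def truth_class_selector(truth: pd.DataFrame, cell_class: str) -> pd.Series:
    """Boolean selector of one analysis class in a ground-truth table."""
    if cell_class in MARKERS:
        return truth[cell_class]
    chat_int = truth["ChAT"] & (truth["diameter_um"] < 25.0)
    if cell_class == "ChAT_interneuron":
        return chat_int
    if cell_class == "ChAT_motor_neuron":
        return truth["ChAT"] & ~chat_int
    if cell_class == "ChAT+GAD67":
        return truth["ChAT"] & truth["GAD67"]
    if cell_class == "Parvalbumin+GAD67":
        return truth["Parvalbumin"] & truth["GAD67"]
    if cell_class == "Parvalbumin+Calbindin":
        return truth["Parvalbumin"] & truth["Calbindin"]
    raise ValueError(f"unknown cell class {cell_class!r}")


def truth_class_counts(truth: pd.DataFrame) -> dict:
    """Ground-truth counts per analysis class (for recovery evaluation)."""
    return {cls: int(truth_class_selector(truth, cls).sum())
            for cls in CELL_CLASSES}


def evaluate_recovery(cells: pd.DataFrame, truth: pd.DataFrame,
                      match_radius_px: float = 3.0) -> dict:
    """Compare detected cells with ground truth, per section and marker.

    Returns per-class detected and true counts plus centroid-error
    statistics over matched (nearest within ``match_radius_px``) pairs.
    """
    from scipy.spatial import cKDTree

    det_counts = {cls: int(class_selector(cells, cls).sum())
                  for cls in CELL_CLASSES}
    true_counts = truth_class_counts(truth)
    errors = []
    sections = truth["section_id"].unique() if "section_id" in truth else [None]
    for sec in sections:
        t = truth if sec is None else truth[truth["section_id"] == sec]
        c = cells if sec is None else cells[cells["section_id"] == sec]
        for marker in MARKERS:
            tm = t[t[marker]]
            cm = c[c["marker"] == marker]
            if tm.empty or cm.empty:
                continue
            tree = cKDTree(cm[["x_px", "y_px"]].to_numpy())
            d, _ = tree.query(tm[["x_px", "y_px"]].to_numpy(),
                              distance_upper_bound=match_radius_px)
            errors.extend(d[np.isfinite(d)])
    errors = np.asarray(errors)
    return {
        "detected": det_counts,
        "truth": true_counts,
        "n_matched": int(errors.size),
        "centroid_error_mean_px": float(errors.mean()) if errors.size else np.nan,
        "centroid_error_max_px": float(errors.max()) if errors.size else np.nan,
    }
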