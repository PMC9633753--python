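"""End-to-end orchestration: simulate/load -> nutrition -> morphometrics ->
dimorphism -> inference, with one config and one seed.

The full analysis mirrors the two-pronged design it implements:

* direct comparisons — stepwise regression of every nutritional,
  behavioral and body variable on shape principal components, MANCOVA of
  the significant set, and a canonical variate analysis between the
  nutrition and shape spaces;
* indirect comparisons — k-means dietary-pattern codes (elbow-selected
  k) followed by per-code accentuated mean faces, SShD decomposition,
  and the normalized inter-landmark panel with ANOVA/Tukey-Kramer and
  Benjamini-Hochberg correction.

Every stage is a thin call into the corresponding module, so pipeline
outputs equal the module calls applied manually in sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .dimorphism import DimorphismAxis, decompose_sshd, results_to_frame
from .io import read_axis, read_behavior, read_body, read_ffq, read_landmarks
from .morpho import (
    GeneralizedProcrustesAnalysis,
    ShapeSpacePCA,
    accentuate_mean,
    centroid_size,
    interlandmark_panel,
    pose_normalize,
)
from .nutrition import (
    BEHAVIOR_CATEGORIES,
    FoodCompositionTable,
    estimate_nutrient_intake,
    profiles_to_frame,
    score_eating_behavior,
)
from .stats import (
    anova_tukey,
    bh_adjust,
    canonical_analysis,
    kmeans_elbow,
    mancova,
    stepwise_select,
)
from .synthio import CohortSpec, generate_cohort, generate_dimorphism_reference

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]

_BODY_VARS = ["weight_kg", "muscle_mass_kg", "fat_mass_kg", "bmi"]


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Either ``cohort_spec`` (simulation) or the five input paths must be
    given.  ``seed`` drives the simulation and the clustering restarts.
    """

    outdir: str = "facediet_run"
    seed: int = 0
    cohort_spec: CohortSpec | None = None
    landmarks_path: str | None = None
    ffq_path: str | None = None
    behavior_path: str | None = None
    body_path: str | None = None
    composition_path: str | None = None
    axis_path: str | None = None
    shape_pca_mode: str = "covariance"
    nutrition_pca_mode: str = "correlation"
    var_threshold: float = 0.90
    alpha_in: float = 0.05
    k_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_restarts: int = 25
    accentuation_weight: float = 5.0
    overwrite: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.var_threshold <= 1):
            raise ValueError("var_threshold must be in (0, 1]")
        if self.accentuation_weight < 0:
            raise ValueError("accentuation_weight must be >= 0")


def _load_inputs(config: RunConfig):
    if config.cohort_spec is not None:
        spec = config.cohort_spec
        spec.seed = config.seed
        cohort = generate_cohort(spec)
        axis = generate_dimorphism_reference(spec)
        return cohort.configurations, cohort.ffq, cohort.behavior, cohort.body, cohort.table, axis, cohort
    needed = {
        "landmarks_path": config.landmarks_path,
        "ffq_path": config.ffq_path,
        "behavior_path": config.behavior_path,
        "body_path": config.body_path,
        "axis_path": config.axis_path,
    }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise ValueError(f"no cohort_spec and missing input paths: {missing}")
    configs = read_landmarks(config.landmarks_path)
    ffq = read_ffq(config.ffq_path)
    behavior = read_behavior(config.behavior_path)
    body = read_body(config.body_path)
    table = (
        FoodCompositionTable.from_csv(config.composition_path)
        if config.composition_path
        else FoodCompositionTable.default()
    )
    axis, _ = read_axis(config.axis_path)
    return configs, ffq, behavior, body, table, axis, None


def _drop_constant(df: pd.DataFrame, stage: str) -> pd.DataFrame:
    sd = df.std(ddof=1)
    const = sd.index[(sd <= 0) | ~np.isfinite(sd)].tolist()
    if const:
        logger.info("%s: dropping constant columns %s", stage, const)
        df = df.drop(columns=const)
    return df


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole chain; write result tables under ``config.outdir``.

    Returns the report bundle (tables and fitted objects) as a dict.
    Refuses to overwrite a directory holding a completed run unless
    ``config.overwrite`` is set.
    """
    out = Path(config.outdir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.overwrite:
        raise FileExistsError(f"completed run already present at {out}; set overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    configs, ffq, behavior, body, table, axis, cohort = _load_inputs(config)
    n = len(configs)
    subject_ids = [c.subject_id for c in configs]
    logger.info("inputs: %d subjects", n)

    # --- nutrition stage ---------------------------------------------------
    profiles = [estimate_nutrient_intake(r, table) for r in ffq]
    nutrient_frame = profiles_to_frame(profiles)
    nutrient_frame.index = subject_ids
    behavior_frame = pd.DataFrame([score_eating_behavior(b) for b in behavior])
    behavior_frame.index = subject_ids
    body_frame = pd.DataFrame([b.to_series() for b in body])
    body_frame.index = subject_ids
    logger.info("nutrition stage: %d nutrient columns", nutrient_frame.shape[1])

    # --- morpho stage ------------------------------------------------------
    posed = [pose_normalize(c) for c in configs]
    gpa_model = GeneralizedProcrustesAnalysis().fit(posed)
    aligned = gpa_model.transform(posed)
    sizes = np.array([centroid_size(c) for c in posed])
    spc_space = ShapeSpacePCA(
        mode=config.shape_pca_mode, var_threshold=config.var_threshold
    ).fit(aligned)
    spc_scores = pd.DataFrame(
        spc_space.transform(aligned),
        index=subject_ids,
        columns=[f"sPC{i + 1}" for i in range(spc_space.n_retained_)],
    )
    logger.info(
        "morpho stage: GPA %d iters, %d sPCs retained", gpa_model.n_iter_, spc_space.n_retained_
    )

    npc_input = _drop_constant(nutrient_frame, "nutrition PCA")
    npc_space = ShapeSpacePCA(
        mode=config.nutrition_pca_mode, var_threshold=config.var_threshold
    ).fit(npc_input.to_numpy())
    npc_scores = pd.DataFrame(
        npc_space.transform(npc_input.to_numpy()),
        index=subject_ids,
        columns=[f"nPC{i + 1}" for i in range(npc_space.n_retained_)],
    )
    logger.info("nutrition PCA: %d nPCs retained", npc_space.n_retained_)

    # --- direct comparisons ------------------------------------------------
    responses = pd.concat(
        [npc_scores, behavior_frame[BEHAVIOR_CATEGORIES], body_frame[_BODY_VARS]],
        axis=1,
    )
    stepwise_rows = []
    significant: list[str] = []
    selected_spcs: set[str] = set()
    for name in responses.columns:
        fit = stepwise_select(
            responses[name], spc_scores, alpha_in=config.alpha_in, response_name=name
        )
        stepwise_rows.append(
            {
                "response": name,
                "selected": ";".join(fit.selected),
                "r_squared": fit.r_squared,
                **{f"coef_{k}": v for k, v in fit.coefficients.items()},
            }
        )
        if fit.selected:
            significant.append(name)
            selected_spcs.update(fit.selected)
    stepwise_table = pd.DataFrame(stepwise_rows)

    mancova_result = None
    if significant and selected_spcs:
        preds = spc_scores[sorted(selected_spcs, key=lambda s: int(s[3:]))]
        if n > len(significant) + preds.shape[1] + 1:
            mancova_result = mancova(responses[significant], preds)

    cca = canonical_analysis(npc_scores, spc_scores)
    # reconstruct the first canonical face axis as a shape vector
    v1 = cca.y_weights[:, 0]
    face_axis = spc_space.inverse_transform(v1.reshape(1, -1))[0] - spc_space.mean_

    # --- indirect comparisons ---------------------------------------------
    features = pd.concat([npc_scores, behavior_frame[BEHAVIOR_CATEGORIES]], axis=1)
    clusters = kmeans_elbow(
        _zscore(features).to_numpy(),
        k_candidates=config.k_candidates,
        seed=config.seed,
        n_restarts=config.n_restarts,
    )
    codes = pd.Series(clusters.codes, index=subject_ids, name="code")
    logger.info("clustering: k=%d selected", clusters.k)

    grand_mean = aligned.mean(axis=0)
    accentuated = {}
    for code in np.unique(clusters.codes):
        gm = aligned[clusters.codes == code].mean(axis=0)
        accentuated[int(code)] = accentuate_mean(gm, grand_mean, config.accentuation_weight)

    sshd_results = decompose_sshd(aligned, sizes, axis, subject_ids)
    sshd_frame = results_to_frame(sshd_results).set_index("subject_id")

    sshd_anova_rows = []
    for col in ("centroid_size", "sshd_total", "sshd_allometric", "sshd_nonallometric"):
        res = anova_tukey(sshd_frame[col].to_numpy(), clusters.codes)
        sshd_anova_rows.append(
            {"variable": col, "f_stat": res.f_stat, "p_value": res.p_value, "eta_sq": res.eta_sq}
        )
    sshd_anova = pd.DataFrame(sshd_anova_rows).set_index("variable")
    sshd_anova["p_bh"] = bh_adjust(sshd_anova["p_value"].to_numpy())

    panel = pd.DataFrame([interlandmark_panel(c) for c in posed])
    panel.index = subject_ids
    panel_rows = []
    for col in panel.columns:
        res = anova_tukey(panel[col].to_numpy(), clusters.codes)
        panel_rows.append(
            {"variable": col, "f_stat": res.f_stat, "p_value": res.p_value, "eta_sq": res.eta_sq}
        )
    panel_anova = pd.DataFrame(panel_rows).set_index("variable")
    panel_anova["p_bh"] = bh_adjust(panel_anova["p_value"].to_numpy())

    # --- write the bundle ---------------------------------------------------
    nutrient_frame.rename_axis("subject_id").to_csv(out / "nutrient_profiles.csv")
    behavior_frame.rename_axis("subject_id").to_csv(out / "behavior_scores.csv")
    body_frame.rename_axis("subject_id").to_csv(out / "body_composition.csv")
    npc_scores.rename_axis("subject_id").to_csv(out / "npc_scores.csv")
    spc_scores.rename_axis("subject_id").to_csv(out / "spc_scores.csv")
    stepwise_table.to_csv(out / "stepwise.csv", index=False)
    if mancova_result is not None:
        mancova_result.coefficients.rename_axis("response").to_csv(out / "mancova_coefficients.csv")
        mancova_result.per_predictor.to_csv(out / "mancova_per_predictor.csv")
    pd.DataFrame(
        {
            "root": np.arange(1, len(cca.correlations) + 1),
            "correlation": cca.correlations,
            "wilks_lambda": cca.wilks,
            "f_stat": cca.f_stats,
            "df1": cca.df1,
            "df2": cca.df2,
            "p_value": cca.p_values,
        }
    ).to_csv(out / "canonical.csv", index=False)
    codes.rename_axis("subject_id").to_csv(out / "cluster_codes.csv")
    clusters.wss_curve.rename_axis("k").rename("wss").to_csv(out / "wss_curve.csv")
    sshd_frame.to_csv(out / "sshd.csv")
    sshd_anova.to_csv(out / "sshd_anova.csv")
    panel.rename_axis("subject_id").to_csv(out / "panel.csv")
    panel_anova.to_csv(out / "panel_anova.csv")
    pd.DataFrame(
        {f"code_{c}": v for c, v in accentuated.items()}
    ).to_csv(out / "accentuated_faces.csv", index=False)
    pd.Series(face_axis).to_csv(out / "canonical_face_axis.csv", header=["value"], index_label="coord")

    manifest = {
        "version": _version,
        "seed": config.seed,
        "n_subjects": n,
        "settings": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("cohort_spec",) and not isinstance(v, (dict,))
        },
        "cohort_spec": None
        if config.cohort_spec is None
        else {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(config.cohort_spec).items()
        },
        "n_spcs": int(spc_space.n_retained_),
        "n_npcs": int(npc_space.n_retained_),
        "gpa_iterations": int(gpa_model.n_iter_),
        "k_selected": int(clusters.k),
        "mancova_wilks_lambda": None if mancova_result is None else mancova_result.wilks_lambda,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "config": config,
        "cohort": cohort,
        "nutrients": nutrient_frame,
        "behavior": behavior_frame,
        "body": body_frame,
        "aligned": aligned,
        "sizes": sizes,
        "gpa": gpa_model,
        "spc_space": spc_space,
        "npc_space": npc_space,
        "spc_scores": spc_scores,
        "npc_scores": npc_scores,
        "stepwise": stepwise_table,
        "mancova": mancova_result,
        "canonical": cca,
        "canonical_face_axis": face_axis,
        "clusters": clusters,
        "codes": codes,
        "accentuated": accentuated,
        "sshd": sshd_frame,
        "sshd_anova": sshd_anova,
        "panel": panel,
        "panel_anova": panel_anova,
        "manifest": manifest,
    }
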