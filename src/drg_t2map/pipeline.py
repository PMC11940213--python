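"""End-to-end pipeline: simulation → fitting → extraction → statistics.

The driver composes the package's stages under one seeded configuration and
writes a manifest listing every artefact with its SHA-256 checksum, so an
identical config + seed reproduces identical outputs.  The global seed fans
out to per-stage seeds through ``numpy.random.SeedSequence.spawn`` — no stage
draws from an unseeded source.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .fitting import FitConfig, fit_volume
from .io import save_json, save_mask, save_multiecho, save_volume
from .phantom import PhantomSpec, generate_phantom, perturb_mask_as_reader
from .reliability import icc_two_way_agreement, test_retest_icc
from .stats import build_cohort_tables, percent_difference, spearman_rho
from .voi import average_readers, compute_volume, extract_voi, summarise_subjects

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    n_phantom_subjects: int = 2
    voi_summary: str = "median"
    seed: int = 0

    def __post_init__(self) -> None:
        # Sub-specs validate themselves on construction; cross-checks here.
        if self.n_phantom_subjects < 0:
            raise ValueError("n_phantom_subjects must be >= 0")
        if self.voi_summary not in ("median", "mean"):
            raise ValueError("voi_summary must be 'median' or 'mean'")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        def build(klass, section):
            params = dict(cfg.get(section, {}))
            return klass(**params)

        return cls(
            cohort=build(CohortSpec, "cohort"),
            phantom=build(PhantomSpec, "phantom"),
            fit=build(FitConfig, "fit"),
            n_phantom_subjects=cfg.get("n_phantom_subjects", 2),
            voi_summary=cfg.get("voi_summary", "median"),
            seed=cfg.get("seed", 0),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline and return the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 4)
    artefacts: list[Path] = []

    def stage(name):
        log.info("stage: %s", name)

    # --- simulate-cohort -------------------------------------------------
    stage("simulate-cohort")
    try:
        cohort_spec = dataclasses.replace(config.cohort, seed=seeds[0])
        subjects, samples, retest = generate_cohort(cohort_spec)
    except Exception as e:
        raise RuntimeError(f"stage simulate-cohort failed: {e}") from e
    subjects.to_csv(out / "subjects.csv", index=False)
    samples.to_csv(out / "drg_samples.csv", index=False)
    retest.to_csv(out / "drg_samples_retest.csv", index=False)
    artefacts += [out / "subjects.csv", out / "drg_samples.csv", out / "drg_samples_retest.csv"]
    log.info(
        "cohort: %d subjects, %d baseline samples, %d retest samples",
        len(subjects), len(samples), len(retest),
    )

    # --- per-subject phantoms: simulate, fit, extract --------------------
    phantom_rows = []
    if config.n_phantom_subjects > 0:
        stage("simulate-phantom + fit-t2 + extract-voi")
        readers = list(config.cohort.readers)
        for i in range(config.n_phantom_subjects):
            try:
                pspec = dataclasses.replace(config.phantom, seed=seeds[1] + i)
                vol, mask, truth = generate_phantom(pspec)
                sid = f"P{i + 1:03d}"
                save_multiecho(out / f"{sid}_multiecho.nii.gz", vol, truth.affine, truth.echo_times_ms)
                artefacts += [out / f"{sid}_multiecho.nii.gz", out / f"{sid}_multiecho_echoes.json"]
                t2map = fit_volume(
                    vol, truth.echo_times_ms, config.fit,
                    affine=truth.affine, voxel_dims_mm=pspec.voxel_dims_mm,
                    params=pspec.echo_params,
                )
                save_volume(out / f"{sid}_t2map.nii.gz", np.nan_to_num(t2map.t2_ms), truth.affine)
                artefacts.append(out / f"{sid}_t2map.nii.gz")
                for reader_idx, reader in enumerate(readers):
                    rmask = perturb_mask_as_reader(mask, reader, seeds[2] + i)
                    if reader_idx == 0:
                        save_mask(out / f"{sid}_mask_{reader}.nii.gz", rmask, truth.affine)
                        artefacts.append(out / f"{sid}_mask_{reader}.nii.gz")
                    for label_name, info in truth.drg_truth.items():
                        level, side = label_name.split("-")
                        t2, _ = extract_voi(t2map, rmask, info["label_value"], config.voi_summary)
                        volume = compute_volume(rmask, info["label_value"], pspec.voxel_dims_mm)
                        phantom_rows.append(
                            {
                                "subject_id": sid, "visit": "baseline", "reader": reader,
                                "level": level, "side": side, "t2_ms": t2,
                                "volume_mm3": volume, "true_t2_ms": info["true_t2_ms"],
                                "true_volume_mm3": info["volume_mm3"],
                            }
                        )
            except Exception as e:
                raise RuntimeError(f"stage phantom[{i}] failed: {e}") from e
        pd.DataFrame(phantom_rows).to_csv(out / "phantom_samples.csv", index=False)
        artefacts.append(out / "phantom_samples.csv")

    # --- reliability ------------------------------------------------------
    stage("reliability")
    try:
        all_samples = pd.concat([samples, retest], ignore_index=True)
        pivot = all_samples.pivot_table(
            index=["subject_id", "visit", "level", "side"], columns="reader", values="t2_ms"
        )
        inter = icc_two_way_agreement(pivot.to_numpy())

        consensus = average_readers(all_samples)
        summaries = summarise_subjects(consensus)
        retest_ids = sorted(retest["subject_id"].unique())
        v1 = summaries[
            (summaries["visit"] == "baseline") & summaries["subject_id"].isin(retest_ids)
        ].sort_values("subject_id")["drg_t2_ms"].to_numpy()
        v2 = summaries[summaries["visit"] == "retest"].sort_values("subject_id")[
            "drg_t2_ms"
        ].to_numpy()
        rr = test_retest_icc(v1, v2)
    except Exception as e:
        raise RuntimeError(f"stage reliability failed: {e}") from e
    save_json(
        out / "reliability.json",
        {
            "inter_rater": dataclasses.asdict(inter),
            "test_retest": dataclasses.asdict(rr),
        },
    )
    consensus.to_csv(out / "drg_samples_consensus.csv", index=False)
    summaries.to_csv(out / "subject_summaries.csv", index=False)
    artefacts += [out / "reliability.json", out / "drg_samples_consensus.csv", out / "subject_summaries.csv"]

    # --- cohort-stats -----------------------------------------------------
    stage("cohort-stats")
    try:
        base = summaries[summaries["visit"] == "baseline"].merge(subjects, on="subject_id")
        tab_sex = build_cohort_tables(base, "sex")
        tab_mut = build_cohort_tables(base, "mutation_class")
        l5 = base["drg_t2_l5_ms"].to_numpy()
        s1 = base["drg_t2_s1_ms"].to_numpy()
        from .stats import wilcoxon_signed_rank

        report = {
            "n_subjects": int(len(base)),
            "median_drg_t2_ms": float(base["drg_t2_ms"].median()),
            "median_drg_vol_mm3": float(base["drg_vol_mm3"].median()),
            "s1_vs_l5_t2_pct": percent_difference(
                float(np.median(s1)), float(np.median(l5))
            ),
            "s1_vs_l5_t2_p": wilcoxon_signed_rank(s1, l5).p_value,
            "bmi_t2_spearman_rho": spearman_rho(
                base["bmi_kg_m2"], base["drg_t2_ms"]
            ).statistic,
        }
    except Exception as e:
        raise RuntimeError(f"stage cohort-stats failed: {e}") from e
    tab_sex.to_csv(out / "table_sex.csv", index=False)
    tab_mut.to_csv(out / "table_mutation.csv", index=False)
    save_json(out / "cohort_report.json", report)
    artefacts += [out / "table_sex.csv", out / "table_mutation.csv", out / "cohort_report.json"]

    # --- manifest ---------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "artefacts": {p.name: _sha256(p) for p in sorted(set(artefacts))},
    }
    save_json(out / "manifest.json", manifest)
    return manifest
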