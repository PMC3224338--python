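"""End-to-end orchestration of a simulated EST survey.

``run_survey`` wires the stages together on simulator output: library
generation, read clean-up, gene tagging (from simulator ground truth),
rarefaction and saturation fitting, redundancy classification on a
simulated unigene-vs-reference alignment set, pairwise library
correlation, and category enrichment on a synthetic hierarchical map.
Every output TSV is stamped with the configuration hash and master seed
so any number in a report can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from estsurvey import (gene_tagging, library_compare, rarefaction, read_prep,
                       redundancy, saturation, simulate)
from estsurvey.exceptions import ConfigError, PipelineError

DEFAULT_LIBRARIES = [
    {"label": "NORM", "platform": "GS20", "normalized": True, "n_reads": 8000},
    {"label": "RAW", "platform": "GS20", "normalized": False, "n_reads": 8000},
]


@dataclass
class PipelineConfig:
    """Structured pipeline configuration (see ``from_yaml``).

    Blocks: ``simulate`` (SimConfig overrides), ``libraries`` (manifest of
    label/platform/normalized/n_reads), ``trim``, ``rarefaction``,
    ``redundancy``, ``enrichment``; top-level ``seed`` and ``out_dir``.
    """

    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(raw=dict(d))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if "seed" not in self.raw:
            raise ConfigError("pipeline config requires an explicit seed")
        labels = [lib["label"] for lib in self.libraries]
        if len(labels) != len(set(labels)):
            raise ConfigError("library labels must be unique")

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.raw.get("out_dir", "survey_out"))

    @property
    def libraries(self) -> list[dict]:
        return self.raw.get("libraries", DEFAULT_LIBRARIES)

    def block(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _stamp(path: Path, df: pd.DataFrame, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# estsurvey config_sha={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_survey(config: PipelineConfig, log=print) -> dict[str, Path]:
    """Run every stage; returns a name -> path map of the report bundle.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        sim_kwargs = config.block("simulate")
        base = simulate.SimConfig(seed=config.seed, **sim_kwargs)
        transcriptome = simulate.build_transcriptome(base)
        weights = simulate.draw_weights(transcriptome, base)
        libraries: dict[str, tuple[list, simulate.SimTruth]] = {}
        for i, lib in enumerate(config.libraries):
            lib_cfg = base.with_(platform=lib.get("platform", base.platform),
                                 n_reads=int(lib.get("n_reads", base.n_reads)),
                                 seed=config.seed + i + 1)
            reads, truth = simulate.generate_reads(
                transcriptome, weights, lib_cfg,
                normalized=bool(lib.get("normalized", False)),
                library=lib["label"])
            libraries[lib["label"]] = (reads, truth)
            fasta = out / f"reads_{lib['label']}.fasta"
            simulate.write_reads_fasta(reads, fasta)
            simulate.write_truth(truth, out / f"truth_reads_{lib['label']}.tsv",
                                 out / f"truth_genes_{lib['label']}.tsv")
            outputs[f"reads_{lib['label']}"] = fasta
            log(f"[simulate] {lib['label']}: {len(reads)} reads, "
                f"{transcriptome.n_genes} genes")

        # --- prep ---------------------------------------------------------
        stage = "prep"
        trim_cfg = read_prep.TrimConfig(**config.block("trim"))
        prep_rows = []
        for label, (reads, _) in libraries.items():
            kept, summary = read_prep.filter_library(reads, trim_cfg)
            row = {"library": label, **summary.as_row()}
            prep_rows.append(row)
            log(f"[prep] {label}: {summary.n_kept}/{summary.n_in} reads kept")
        prep_path = out / "prep_summary.tsv"
        _stamp(prep_path, pd.DataFrame(prep_rows), config)
        outputs["prep_summary"] = prep_path

        # --- tag (from simulator ground truth) ----------------------------
        stage = "tag"
        profiles = {}
        for label, (_, truth) in libraries.items():
            profile = gene_tagging.profile_from_labels(
                truth.reads["gene_id"], library=label)
            profiles[label] = profile
            path = out / f"profile_{label}.tsv"
            gene_tagging.write_profile(profile, path)
            outputs[f"profile_{label}"] = path
            log(f"[tag] {label}: {len(profile.counts)} genes tagged")

        # --- rarefy + fit ---------------------------------------------------
        stage = "rarefy"
        rare_cfg = config.block("rarefaction")
        thresholds = tuple(rare_cfg.get("thresholds", (1, 5, 10)))
        grid_points = int(rare_cfg.get("grid_points", 12))
        reps = int(rare_cfg.get("reps", 5))
        curve_sets = {}
        pools = {label: rarefaction.ReadPool.from_profile(p)
                 for label, p in profiles.items()}
        combined = None
        for pool in pools.values():
            combined = pool if combined is None else combined.combine(pool)
        pools["all"] = combined
        for label, pool in pools.items():
            grid = rarefaction.sample_size_grid(pool.n_reads, grid_points)
            curves = rarefaction.build_curves(pool, grid, thresholds, reps,
                                              seed=config.seed)
            curve_sets[label] = curves
            path = out / f"rarefaction_{label}.tsv"
            rarefaction.curves_to_tsv(curves, path)
            outputs[f"rarefaction_{label}"] = path

        stage = "fit"
        fits = saturation.fit_table(curve_sets)
        fit_path = out / "saturation_fits.tsv"
        _stamp(fit_path, fits, config)
        outputs["saturation_fits"] = fit_path
        log(f"[fit] {len(fits)} saturation fits")

        # --- redundancy -----------------------------------------------------
        stage = "redundancy"
        red_cfg = config.block("redundancy")
        aln = simulate.simulate_alignment_set(
            ref_length=int(red_cfg.get("ref_length", 600)),
            n_queries=int(red_cfg.get("n_unigenes", 60)),
            n_variant_positions=int(red_cfg.get("n_variant_positions", 3)),
            error_rate=float(red_cfg.get("error_rate", 0.005)),
            seed=config.seed)
        segments = redundancy.segments_from_ungapped(
            aln.queries, aln.ref_name, len(aln.ref_seq))
        pileup = redundancy.pileup_columns(segments, aln.ref_seq,
                                           reference=aln.ref_name)
        counts = redundancy.classify_positions(pileup)
        table = redundancy.summarize_table([counts])
        red_path = out / "redundancy_table.tsv"
        _stamp(red_path, table, config)
        outputs["redundancy_table"] = red_path
        log(f"[redundancy] {counts.n_variant} variant / {counts.n_error} "
            f"error positions on {counts.length} bp")

        # --- compare --------------------------------------------------------
        stage = "compare"
        universe = config.block("compare").get("universe", "both")
        mat = library_compare.correlation_matrix(list(profiles.values()),
                                                 universe=universe)
        cmp_path = out / "correlation_matrix.tsv"
        _stamp(cmp_path, mat.rename_axis("library").reset_index(), config)
        outputs["correlation_matrix"] = cmp_path

        # --- enrich ---------------------------------------------------------
        stage = "enrich"
        from estsurvey import enrichment as enr

        enr_cfg = config.block("enrichment")
        n_cats = int(enr_cfg.get("n_categories", 12))
        rng = np.random.default_rng([config.seed, 99])
        genes = transcriptome.gene_ids
        top = rng.integers(1, n_cats + 1, size=len(genes))
        sub = rng.integers(1, 4, size=len(genes))
        cat_map = {g: {f"{t}.{s}"} for g, t, s in zip(genes, top, sub)}
        cat_map = enr.propagate_hierarchy(cat_map)
        lib_sets = {label: p.genes() for label, p in profiles.items()}
        background = set().union(*lib_sets.values())
        zmat = enr.z_matrix(lib_sets, background, cat_map,
                            fdr=bool(enr_cfg.get("fdr", True)))
        enr_path = out / "enrichment_z.tsv"
        _stamp(enr_path, zmat.rename_axis("category").reset_index(), config)
        outputs["enrichment_z"] = enr_path
        log(f"[enrich] {zmat.shape[0]} categories x {zmat.shape[1]} libraries")

        # --- manifest -------------------------------------------------------
        stage = "manifest"
        manifest = {"config_sha": config.config_hash(), "seed": config.seed,
                    "outputs": {k: str(v) for k, v in outputs.items()}}
        man_path = out / "run_manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        outputs["manifest"] = man_path
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, str(exc)) from exc
    return outputs
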