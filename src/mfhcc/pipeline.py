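"""End-to-end orchestration of the molecular and pathology analyses.

``run_molecular`` takes a cohort directory (MAF, segment tables + sidecars,
clinical CSV, reference FASTA) and produces per-lesion burden summaries and
signature exposures, per-patient clonality calls and pair trees, and the
cohort-level group comparisons, survival analysis and molecular-vs-pathology
concordance.  ``run_histo`` does the pathology arm on per-focus tile
directories.  Both are deterministic for a fixed config and write flat TSV /
JSON / newick outputs plus a manifest for exact replay.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import burden_metrics as bm
from . import clonality as cl
from . import cohort_stats as cs
from . import histo_features as hf
from . import signatures as sg
from . import variant_model as vm

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineInputError", "StageError", "run_molecular", "run_histo"]

DEFAULT_GENE_TESTS = ("TP53", "ARID1A")


class PipelineInputError(ValueError):
    """Inputs missing or unparseable before any analysis stage ran."""


class StageError(RuntimeError):
    """A stage failed; the message names the stage and the offending sample."""


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, with the published defaults."""

    maf: Optional[str] = None            # MAF file or directory of *.maf
    seg_dir: Optional[str] = None
    clinical: Optional[str] = None
    reference: Optional[str] = None      # FASTA (indexed on first use)
    signature_tsv: Optional[str] = None  # None -> bundled synthetic catalogue
    tiles_dir: Optional[str] = None
    outdir: str = "mfhcc_out"
    jaccard_threshold: float = cl.DEFAULT_JACCARD_THRESHOLD
    nonsilent_only_jaccard: bool = False
    cds_mb: float = bm.DEFAULT_CDS_MB
    msi_threshold: float = bm.DEFAULT_MSI_THRESHOLD
    min_exposure: float = sg.DEFAULT_MIN_EXPOSURE
    named_signatures: Sequence[int] = sg.DEFAULT_NAMED_SIGNATURES
    gene_tests: Sequence[str] = DEFAULT_GENE_TESTS
    correlation_mode: str = "standardized"  # or "raw"
    mpp: float = hf.DEFAULT_MPP
    seed: int = 0


def _read_maf_input(maf_path) -> dict[str, list[vm.Variant]]:
    path = Path(maf_path)
    if path.is_dir():
        files = sorted(path.glob("*.maf"))
        if not files:
            raise PipelineInputError(f"no *.maf files in {path}")
        groups: dict[str, list[vm.Variant]] = {}
        for f in files:
            for sample, variants in vm.read_maf(f).items():
                groups.setdefault(sample, []).extend(variants)
        return groups
    if not path.exists():
        raise PipelineInputError(f"MAF input {path} does not exist")
    return vm.read_maf(path)


def _lesion_profile(
    patient_id: str, lesion_id: str, groups: Mapping, seg_dir: Optional[Path]
) -> vm.LesionProfile:
    if lesion_id not in groups:
        raise PipelineInputError(f"lesion {lesion_id} absent from MAF input")
    segments: list[vm.CnvSegment] = []
    ploidy, msi = 2.0, 0.0
    if seg_dir is not None:
        seg_file = seg_dir / f"{lesion_id}.seg"
        if seg_file.exists():
            segments = vm.read_segments(seg_file)
        sidecar = seg_dir / f"{lesion_id}.json"
        if sidecar.exists():
            meta = vm.read_sample_sidecar(sidecar)
            ploidy = float(meta["ploidy"])
            msi = float(meta.get("msi_score", 0.0))
    return vm.LesionProfile(
        patient_id=patient_id, lesion_id=lesion_id, variants=list(groups[lesion_id]),
        segments=segments, ploidy=ploidy, msi_score=msi,
    )


def run_molecular(config: RunConfig) -> dict:
    """Run the molecular arm; returns a results bundle and writes the output TSVs."""
    if config.maf is None or config.clinical is None:
        raise PipelineInputError("run_molecular needs at least --maf and --clinical")
    outdir = Path(config.outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)

    groups = _read_maf_input(config.maf)
    clinical = vm.read_clinical(config.clinical)
    seg_dir = Path(config.seg_dir) if config.seg_dir else None

    reference = None
    if config.reference:
        import pyfaidx

        reference = pyfaidx.Fasta(config.reference)
    sig_matrix = sg.load_signature_matrix(config.signature_tsv)

    pairs: list[vm.PatientPair] = []
    for row in clinical.itertuples(index=False):
        try:
            pairs.append(
                vm.PatientPair(
                    patient_id=row.patient_id,
                    lesion_a=_lesion_profile(row.patient_id, row.lesion_a_id, groups, seg_dir),
                    lesion_b=_lesion_profile(row.patient_id, row.lesion_b_id, groups, seg_dir),
                    pfs_months=float(row.pfs_months),
                    event=bool(row.event),
                    pathology_call=str(row.pathology_call),
                )
            )
        except PipelineInputError:
            raise
        except Exception as exc:
            raise StageError(f"stage=load patient={row.patient_id}: {exc}") from exc

    # --- per-lesion burden + signatures
    burden_rows, exposure_rows = [], []
    for pair in pairs:
        for lesion in (pair.lesion_a, pair.lesion_b):
            try:
                summary = bm.BurdenSummary(
                    lesion_id=lesion.lesion_id,
                    tmb=bm.compute_tmb(lesion.variants, config.cds_mb),
                    cnv_score=bm.cnv_score(lesion.segments, lesion.ploidy),
                    msi_status=bm.msi_status(lesion.msi_score, config.msi_threshold),
                    ploidy=lesion.ploidy,
                )
            except Exception as exc:
                raise StageError(f"stage=burden sample={lesion.lesion_id}: {exc}") from exc
            burden_rows.append(
                {"lesion_id": summary.lesion_id, "tmb": summary.tmb,
                 "cnv_score": summary.cnv_score, "msi_status": summary.msi_status,
                 "msi_score": lesion.msi_score, "ploidy": summary.ploidy}
            )
            if reference is not None:
                snvs = [v for v in lesion.variants if v.is_snv]
                if snvs:
                    try:
                        cv = sg.build_context_vector(snvs, reference)
                        exp = sg.fit_signatures(cv, sig_matrix, config.min_exposure)
                        reduced = sg.reduce_exposures(exp, config.named_signatures)
                    except Exception as exc:
                        raise StageError(
                            f"stage=signatures sample={lesion.lesion_id}: {exc}"
                        ) from exc
                    exposure_rows.append(
                        {"lesion_id": lesion.lesion_id, "n_snvs": len(snvs),
                         **exp.exposures.to_dict(), **reduced.to_dict()}
                    )

    # --- per-patient clonality + trees
    results = []
    for pair in pairs:
        try:
            keys_a, keys_b = _pair_key_sets(pair, config.nonsilent_only_jaccard)
            res = cl.classify_sets(pair.patient_id, keys_a, keys_b, config.jaccard_threshold)
        except Exception as exc:
            raise StageError(f"stage=clonality patient={pair.patient_id}: {exc}") from exc
        results.append(res)
        shared_keys, _, _ = cl.shared_private_partition(keys_a, keys_b)
        trunk_genes = sorted(
            {v.gene for v in pair.lesion_a.variants
             if vm.variant_key(v) in shared_keys and v.gene}
        )
        tree = cl.build_pair_tree(
            res, label_a=pair.lesion_a.lesion_id, label_b=pair.lesion_b.lesion_id,
            trunk_genes=trunk_genes,
        )
        (outdir / "trees" / f"{pair.patient_id}.nwk").write_text(tree.newick + "\n")

    clonality_df = cl.results_to_frame(results)
    burden_df = pd.DataFrame(burden_rows)
    exposures_df = pd.DataFrame(exposure_rows)

    # --- cohort statistics
    calls = dict(zip(clonality_df["patient_id"], clonality_df["call"]))
    lesion_group = {}
    for pair in pairs:
        for lesion in (pair.lesion_a, pair.lesion_b):
            lesion_group[lesion.lesion_id] = calls[pair.patient_id]
    burden_df["group"] = burden_df["lesion_id"].map(lesion_group)

    comparison_rows = []
    for variable in ("tmb", "cnv_score", "msi_score", "ploidy"):
        by = {g: burden_df.loc[burden_df["group"] == g, variable].to_numpy()
              for g in ("IM", "MO")}
        if min(len(v) for v in by.values()) == 0:
            continue
        u, p = cs.mann_whitney(by["IM"], by["MO"])
        comparison_rows.append(
            {"variable": variable, "test": "mann-whitney",
             "n_im": len(by["IM"]), "n_mo": len(by["MO"]),
             "mean_im": float(by["IM"].mean()), "mean_mo": float(by["MO"].mean()),
             "statistic": u, "p_value": p}
        )
    comparisons_df = pd.DataFrame(comparison_rows)

    gene_rows = []
    sample_genes = {
        lesion.lesion_id: {v.gene for v in lesion.variants if v.gene}
        for pair in pairs for lesion in (pair.lesion_a, pair.lesion_b)
    }
    labels = [lesion_group[s] for s in sample_genes]
    if len(set(labels)) == 2:
        for gene in config.gene_tests:
            flags = [gene in genes for genes in sample_genes.values()]
            table = cs.gene_frequency_table(labels, flags)
            odds, p = cs.fisher_exact(table)
            gene_rows.append(
                {"gene": gene,
                 "im_mutated": int(table[0, 0]), "im_wildtype": int(table[0, 1]),
                 "mo_mutated": int(table[1, 0]), "mo_wildtype": int(table[1, 1]),
                 "odds_ratio": odds, "p_value": p, "test": "fisher-exact"}
            )
    gene_df = pd.DataFrame(gene_rows)

    times = [pair.pfs_months for pair in pairs]
    events = [pair.event for pair in pairs]
    pt_groups = [calls[pair.patient_id] for pair in pairs]
    survival = {"logrank_chi2": float("nan"), "logrank_p": float("nan")}
    curves: dict[str, pd.DataFrame] = {}
    if len(set(pt_groups)) == 2:
        curves, chi2, p = cs.km_logrank(times, events, pt_groups)
        survival = {"logrank_chi2": chi2, "logrank_p": p}

    pathology = {pair.patient_id: pair.pathology_call for pair in pairs}
    concordance_result = None
    if any(v != "unknown" for v in pathology.values()):
        concordance_result = cs.concordance(calls, pathology)

    # --- write outputs
    clonality_df.to_csv(outdir / "clonality.tsv", sep="\t", index=False)
    burden_df.to_csv(outdir / "burden.tsv", sep="\t", index=False)
    if not exposures_df.empty:
        exposures_df.to_csv(outdir / "exposures.tsv", sep="\t", index=False)
    comparisons_df.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
    gene_df.to_csv(outdir / "gene_tests.tsv", sep="\t", index=False)
    surv_rows = [
        {"group": g, "time": t, "survival": s}
        for g, curve in curves.items()
        for t, s in zip(curve["time"], curve["survival"])
    ]
    pd.DataFrame(surv_rows).to_csv(outdir / "survival.tsv", sep="\t", index=False)
    concordance_payload = None
    if concordance_result is not None:
        concordance_payload = {
            "n_total": concordance_result.n_total,
            "n_agree": concordance_result.n_agree,
            "percent_agreement": concordance_result.percent_rounded,
        }
        with open(outdir / "concordance.json", "w") as fh:
            json.dump(concordance_payload, fh, indent=1)
    _write_manifest(config, outdir, stage="molecular")

    return {
        "clonality": clonality_df,
        "burden": burden_df,
        "exposures": exposures_df,
        "comparisons": comparisons_df,
        "gene_tests": gene_df,
        "survival": survival,
        "survival_curves": curves,
        "concordance": concordance_payload,
        "calls": calls,
    }


def _pair_key_sets(pair: vm.PatientPair, nonsilent_only: bool):
    def keys(lesion: vm.LesionProfile):
        vs = lesion.variants
        if nonsilent_only:
            vs = [v for v in vs if vm.is_nonsilent(v.classification)]
        return frozenset(vm.variant_key(v) for v in vs)

    return keys(pair.lesion_a), keys(pair.lesion_b)


def run_histo(config: RunConfig, labels: Optional[Mapping[str, str]] = None) -> dict:
    """Run the pathology arm on per-focus tile directories.

    ``tiles_dir`` holds one subdirectory per lesion (named ``<lesion_id>``)
    with PNG/TIFF tiles inside.  All tiles are normalized against one cohort
    reference tile, nuclei from all tiles of a focus are pooled before
    image-level feature computation, and per-patient inter-focus
    correlations are computed on cohort-standardized features.  A focus with
    no segmentable nuclei is recorded as missing, not fatal.
    """
    if config.tiles_dir is None or config.clinical is None:
        raise PipelineInputError("run_histo needs --tiles-dir and --clinical")
    tiles_root = Path(config.tiles_dir)
    if not tiles_root.is_dir():
        raise PipelineInputError(f"tiles dir {tiles_root} does not exist")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical = vm.read_clinical(config.clinical)

    lesion_dirs = sorted(d for d in tiles_root.iterdir() if d.is_dir())
    if not lesion_dirs:
        raise PipelineInputError(f"no per-lesion tile directories in {tiles_root}")

    def _load_tiles(d: Path) -> list[hf.Tile]:
        tiles = []
        for f in sorted(list(d.glob("*.png")) + list(d.glob("*.tif*"))):
            arr = np.asarray(Image.open(f).convert("RGB"))
            tiles.append(hf.Tile(pixels=arr, mpp=config.mpp, tile_id=f"{d.name}/{f.name}"))
        return tiles

    all_tiles = {d.name: _load_tiles(d) for d in lesion_dirs}
    reference_tile = next(
        (ts[0] for ts in all_tiles.values() if ts), None
    )
    if reference_tile is None:
        raise PipelineInputError("no tiles found under any lesion directory")

    vectors: dict[str, pd.Series] = {}
    missing: list[str] = []
    for lesion_id, tiles in all_tiles.items():
        records = []
        for tile in tiles:
            try:
                norm = hf.macenko_normalize(tile, reference_tile)
                seg = hf.segment_nuclei(norm)
                records.append(hf.nucleus_features(seg, norm))
            except Exception as exc:
                raise StageError(f"stage=histo sample={tile.tile_id}: {exc}") from exc
        pooled = pd.concat(records, ignore_index=True) if records else pd.DataFrame()
        if pooled.empty:
            log.warning("focus %s: no nuclei segmented; recorded as missing", lesion_id)
            missing.append(lesion_id)
            continue
        vectors[lesion_id] = hf.image_level_features(pooled)

    features_df = pd.DataFrame(vectors).T
    features_df.index.name = "lesion_id"
    features_df.to_csv(outdir / "image_features.tsv", sep="\t")

    cohort_mean = features_df.mean(axis=0)
    cohort_std = features_df.std(axis=0, ddof=0)
    standardized = config.correlation_mode == "standardized"

    corr_rows = []
    for row in clinical.itertuples(index=False):
        a, b = str(row.lesion_a_id), str(row.lesion_b_id)
        if a not in vectors or b not in vectors:
            continue
        r = hf.focus_pair_correlation(
            vectors[a], vectors[b],
            cohort_mean=cohort_mean if standardized else None,
            cohort_std=cohort_std if standardized else None,
        )
        entry = {"patient_id": row.patient_id, "correlation": r}
        if labels and row.patient_id in labels:
            entry["group"] = labels[row.patient_id]
        corr_rows.append(entry)
    corr_df = pd.DataFrame(corr_rows)
    corr_df.to_csv(outdir / "correlations.tsv", sep="\t", index=False)

    comparison = None
    if "group" in corr_df.columns and corr_df["group"].nunique() == 2:
        by = {g: corr_df.loc[corr_df["group"] == g, "correlation"].to_numpy()
              for g in corr_df["group"].unique()}
        (g1, v1), (g2, v2) = sorted(by.items())
        u, p = cs.mann_whitney(v1, v2)
        comparison = {"groups": [g1, g2], "test": "mann-whitney", "statistic": u,
                      "p_value": p, "mean": {g1: float(v1.mean()), g2: float(v2.mean())}}
        with open(outdir / "correlation_comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=1)
    _write_manifest(config, outdir, stage="histo")
    return {"features": features_df, "correlations": corr_df,
            "missing_foci": missing, "comparison": comparison}


def _write_manifest(config: RunConfig, outdir: Path, stage: str) -> None:
    payload = {"stage": stage, "config": dataclasses.asdict(config)}
    payload["config"]["named_signatures"] = list(config.named_signatures)
    payload["config"]["gene_tests"] = list(config.gene_tests)
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
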