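"""Stage orchestration: atlas → quantify → specificity → qc → motifs.

Each stage reads its inputs from the output directory of the stages
before it (or from the configured input files), writes plain-text outputs,
and appends to a manifest of SHA-256 hashes so reruns can be verified
bit-identical. Stage logging goes to stderr.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import motifs as motifs_mod
from . import qc as qc_mod
from . import quantify as quant_mod
from . import specificity as spec_mod
from .config import PipelineConfig
from .intervals import (
    GenomeSequence,
    GenomicInterval,
    TSSAnnotation,
    read_bed,
    write_bed,
)

STAGES = ("atlas", "quantify", "specificity", "qc", "motifs")


class StageError(RuntimeError):
    pass


def _log(stage: str, message: str) -> None:
    print(f"[atacatlas:{stage}] {message}", file=sys.stderr)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] | None = None,
) -> dict[str, str]:
    """Run the requested stages in dependency order.

    Returns the manifest (relative output path -> sha256). Outputs of a
    stage are rewritten deterministically; a rerun with identical inputs
    and seed produces identical hashes.
    """
    requested = list(stages) if stages else list(STAGES)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise StageError(f"unknown stage(s) {unknown}; valid: {STAGES}")
    ordered = [s for s in STAGES if s in requested]
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    state: dict[str, object] = {}
    for stage in ordered:
        t0 = time.perf_counter()
        outputs = _RUNNERS[stage](config, outdir, state)
        for p in outputs:
            manifest[str(p.relative_to(outdir))] = _sha256(p)
        _log(stage, f"done in {time.perf_counter() - t0:.2f}s, "
                    f"{len(outputs)} output file(s)")
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _load_atlas(config: PipelineConfig, outdir: Path) -> atlas_mod.PeakAtlas:
    """Rebuild the annotated atlas object from a prior atlas stage run."""
    table = pd.read_csv(outdir / "annotation.tsv", sep="\t")
    peaks = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.peak_id, 0.0)
        for r in table.itertuples()
    ]
    provenance = [
        frozenset(str(p).split(",")) if pd.notna(p) and str(p) else frozenset()
        for p in table["provenance"]
    ]
    distances = [
        None if pd.isna(d) else int(d) for d in table["tss_distance"]
    ]
    genes = [None if pd.isna(g) else str(g) for g in table["nearest_gene"]]
    classes = [None if pd.isna(c) else str(c) for c in table["region_class"]]
    return atlas_mod.PeakAtlas(
        peaks, provenance, distances, classes, genes, config.proximal_cutoff
    )


def _stage_atlas(
    config: PipelineConfig, outdir: Path, state: dict
) -> list[Path]:
    per_tissue: dict[str, list[GenomicInterval]] = {}
    sheet = config.sample_sheet
    peak_files = config.peak_files()
    for tissue, sub in sheet.groupby("tissue"):
        reps = [
            read_bed(peak_files[s])
            for s in sub.sort_values("replicate")["sample_id"]
        ]
        kept = reps[0]
        for other in reps[1:]:
            kept = atlas_mod.reproducible_peaks(
                kept, other, mode=config.replicate_mode
            )
        per_tissue[tissue] = kept
        _log("atlas", f"{tissue}: {len(kept)} reproducible peaks")
    built = atlas_mod.build_standard_peaks(per_tissue)
    tss = TSSAnnotation.from_bed(config.tss)
    annotated = atlas_mod.annotate_atlas(built, tss, config.proximal_cutoff)
    state["atlas"] = annotated
    bed_path = outdir / "standard_peaks.bed"
    annotated.to_bed(bed_path)
    table_path = outdir / "annotation.tsv"
    annotated.annotation_table().to_csv(table_path, sep="\t", index=False)
    return [bed_path, table_path]


def _stage_quantify(
    config: PipelineConfig, outdir: Path, state: dict
) -> list[Path]:
    atl = state.get("atlas") or _load_atlas(config, outdir)
    state["atlas"] = atl
    cm = quant_mod.build_count_matrix(atl, config.fragment_files())
    norm = quant_mod.normalize_rpm(cm, pseudocount=config.pseudocount)
    corr = quant_mod.sample_correlation(norm)
    order, _Z = quant_mod.cluster_samples(corr.dropna(axis=0, how="all").dropna(axis=1, how="all"))
    state["counts"], state["norm"], state["corr"] = cm, norm, corr
    paths = []
    for name, df in (
        ("counts.tsv", cm.counts),
        ("rpm.tsv", norm.rpm),
        ("correlations.tsv", corr),
    ):
        p = outdir / name
        df.to_csv(p, sep="\t", float_format="%.6g")
        paths.append(p)
    lib_path = outdir / "library_sizes.tsv"
    cm.library_sizes.to_csv(lib_path, sep="\t", header=["library_size"])
    order_path = outdir / "sample_order.txt"
    order_path.write_text("\n".join(order) + "\n")
    return paths + [lib_path, order_path]


def _require_norm(config: PipelineConfig, outdir: Path, state: dict):
    if "norm" not in state:
        rpm_path = outdir / "rpm.tsv"
        if not rpm_path.exists():
            raise StageError("quantify outputs missing; run the quantify stage")
        rpm = pd.read_csv(rpm_path, sep="\t", index_col=0)
        lib = pd.read_csv(
            outdir / "library_sizes.tsv", sep="\t", index_col=0
        )["library_size"]
        state["norm"] = quant_mod.NormalizedMatrix(
            rpm, np.log10(rpm + config.pseudocount), lib, config.pseudocount
        )
    return state["norm"]


def _stage_specificity(
    config: PipelineConfig, outdir: Path, state: dict
) -> list[Path]:
    norm = _require_norm(config, outdir, state)
    atl = state.get("atlas") or _load_atlas(config, outdir)
    state["atlas"] = atl
    sample_to_tissue = config.sample_to_tissue()
    paths = []
    results = {}
    for analysis in config.analyses:
        samples = [
            s for s in norm.rpm.columns
            if sample_to_tissue[s] in analysis.tissues
        ]
        mapping = {
            s: analysis.merge.get(sample_to_tissue[s], sample_to_tissue[s])
            for s in samples
        }
        ei = spec_mod.tissue_profile(norm.rpm[samples], mapping)
        result = spec_mod.call_specific_peaks(ei, analysis.threshold)
        results[analysis.name] = result
        table_path = outdir / f"specificity_{analysis.name}.tsv"
        result.table().to_csv(table_path, sep="\t", float_format="%.6g")
        paths.append(table_path)
        by_id = {p.name: p for p in atl.peaks}
        for tissue in result.ri.columns:
            ids = result.specific_peaks(tissue)
            bed = outdir / f"specific_{analysis.name}_{tissue}.bed"
            write_bed([by_id[i] for i in ids if i in by_id], bed)
            paths.append(bed)
        _log(
            "specificity",
            f"{analysis.name}: {int(result.is_specific.sum())} specific peaks "
            f"of {len(result.h)} at H < {analysis.threshold}",
        )
    state["specificity"] = results
    return paths


def _stage_qc(config: PipelineConfig, outdir: Path, state: dict) -> list[Path]:
    atl = state.get("atlas") or _load_atlas(config, outdir)
    state["atlas"] = atl
    tss = TSSAnnotation.from_bed(config.tss)
    paths = []
    scores = {}
    for sample, frag_path in config.fragment_files().items():
        fragments = read_bed(frag_path)
        profile = qc_mod.tss_enrichment(
            fragments,
            tss,
            half_width=config.tss_half_width,
            bin_size=config.tss_bin_size,
            flank=config.tss_flank,
        )
        scores[sample] = profile.score
        p = outdir / f"tss_enrichment_{sample}.tsv"
        profile.table().to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths.append(p)
    score_path = outdir / "tss_enrichment_scores.tsv"
    pd.Series(scores, name="tss_enrichment_score").rename_axis("sample_id").to_csv(
        score_path, sep="\t", float_format="%.6g"
    )
    paths.append(score_path)
    props = qc_mod.region_proportions(atl)
    prop_path = outdir / "region_proportions.tsv"
    pd.DataFrame(
        {
            "region_class": list(props.fractions),
            "count": [props.counts[c] for c in props.fractions],
            "fraction": [props.fractions[c] for c in props.fractions],
        }
    ).to_csv(prop_path, sep="\t", index=False, float_format="%.6g")
    paths.append(prop_path)
    return paths


def _stage_motifs(
    config: PipelineConfig, outdir: Path, state: dict
) -> list[Path]:
    if config.genome is None or config.pwms is None:
        raise StageError("motifs stage requires genome and pwms in the config")
    atl = state.get("atlas") or _load_atlas(config, outdir)
    if "specificity" not in state:
        raise StageError("motifs stage requires the specificity stage")
    genome = GenomeSequence.from_fasta(config.genome)
    pwms = motifs_mod.read_jaspar(
        config.pwms, threshold_fraction=config.pwm_threshold_fraction
    )
    by_id = {p.name: p for p in atl.peaks}
    rng = np.random.default_rng(config.seed)
    paths = []
    for name, result in state["specificity"].items():  # type: ignore[union-attr]
        foreground = {}
        specific_ids: set[str] = set()
        for tissue in result.ri.columns:
            ids = [i for i in result.specific_peaks(tissue) if i in by_id]
            specific_ids.update(ids)
            foreground[tissue] = [genome.extract(by_id[i]) for i in ids]
        bg_ids = sorted(set(by_id) - specific_ids)
        fg_max = max((len(v) for v in foreground.values()), default=0)
        bg_seqs = motifs_mod.select_background(
            [genome.extract(by_id[i]) for i in bg_ids],
            fg_max,
            multiple=config.background_multiple,
            rng=rng,
        )
        matrix = motifs_mod.motif_enrichment(foreground, bg_seqs, pwms)
        mat_path = outdir / f"motif_enrichment_{name}.tsv"
        matrix.neg_log10.rename_axis("motif").to_csv(
            mat_path, sep="\t", float_format="%.6g"
        )
        paths.append(mat_path)
        top = motifs_mod.top_motifs(matrix, k=15)
        top_path = outdir / f"top_motifs_{name}.tsv"
        with open(top_path, "w") as fh:
            fh.write("tissue\trank\tmotif\tneg_log10_p\n")
            for tissue in sorted(top):
                for rank, motif in enumerate(top[tissue], start=1):
                    nl = matrix.neg_log10.loc[motif, tissue]
                    fh.write(f"{tissue}\t{rank}\t{motif}\t{nl:.6g}\n")
        paths.append(top_path)
    return paths


_RUNNERS = {
    "atlas": _stage_atlas,
    "quantify": _stage_quantify,
    "specificity": _stage_specificity,
    "qc": _stage_qc,
    "motifs": _stage_motifs,
}
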