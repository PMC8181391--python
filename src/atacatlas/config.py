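"""Pipeline configuration: one flat YAML file plus a sample sheet TSV.

The sample sheet has columns sample_id, tissue, replicate, sex, peaks,
fragments (paths relative to the sheet's directory). The YAML names the
sheet, the genome FASTA, the TSS BED, the PWM file, the output directory,
the thresholds, and optional specificity analyses (named tissue subsets
with their own entropy threshold and an optional tissue-merge mapping,
e.g. collapsing cortex sub-regions into one tissue). Validation collects
every error before failing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml


class ConfigError(ValueError):
    """Configuration problems; carries the full list of errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass
class AnalysisSpec:
    """One specificity invocation: a tissue set with its own threshold."""

    name: str
    tissues: list[str]
    threshold: float
    merge: dict[str, str] = field(default_factory=dict)  # tissue -> merged name

    def effective_tissues(self) -> list[str]:
        return sorted({self.merge.get(t, t) for t in self.tissues})


@dataclass
class PipelineConfig:
    sample_sheet: pd.DataFrame
    genome: Path | None
    tss: Path
    pwms: Path | None
    outdir: Path
    seed: int = 0
    proximal_cutoff: int = 2000
    pseudocount: float = 1.0
    pwm_threshold_fraction: float = 0.6
    background_multiple: float = 5.0
    replicate_mode: str = "reference"
    analyses: list[AnalysisSpec] = field(default_factory=list)
    tss_half_width: int = 2000
    tss_bin_size: int = 10
    tss_flank: int = 100

    @property
    def samples(self) -> list[str]:
        return list(self.sample_sheet["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sample_sheet["tissue"].unique())

    def sample_to_tissue(self) -> dict[str, str]:
        return dict(
            zip(self.sample_sheet["sample_id"], self.sample_sheet["tissue"])
        )

    def peak_files(self) -> dict[str, Path]:
        return dict(zip(self.samples, map(Path, self.sample_sheet["peaks"])))

    def fragment_files(self) -> dict[str, Path]:
        return dict(
            zip(self.samples, map(Path, self.sample_sheet["fragments"]))
        )


_SHEET_COLUMNS = ["sample_id", "tissue", "replicate", "sex", "peaks", "fragments"]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config, collecting all errors.

    Raises :class:`ConfigError` carrying every problem found, not just the
    first one.
    """
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def resolve(key: str, required: bool) -> Path | None:
        value = raw.get(key)
        if value is None:
            if required:
                errors.append(f"missing required key {key!r}")
            return None
        p = base / value
        if not p.exists():
            errors.append(f"{key}: file not found: {p}")
        return p

    sheet_path = resolve("sample_sheet", required=True)
    sheet = pd.DataFrame(columns=_SHEET_COLUMNS)
    if sheet_path is not None and sheet_path.exists():
        sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
        missing_cols = [c for c in _SHEET_COLUMNS if c not in sheet.columns]
        if missing_cols:
            errors.append(f"sample sheet missing columns {missing_cols}")
        else:
            dup = sheet["sample_id"][sheet["sample_id"].duplicated()].tolist()
            for d in sorted(set(dup)):
                errors.append(f"duplicate sample id {d!r}")
            for col in ("peaks", "fragments"):
                sheet[col] = [str(sheet_path.parent / p) for p in sheet[col]]
                for sample, p in zip(sheet["sample_id"], sheet[col]):
                    if not Path(p).exists():
                        errors.append(
                            f"sample {sample!r}: {col} file not found: {p}"
                        )

    tss_path = resolve("tss", required=True)
    genome_path = resolve("genome", required=False)
    pwm_path = resolve("pwms", required=False)

    tissues_present: dict[str, int] = {}
    if "tissue" in sheet.columns:
        tissues_present = sheet["tissue"].value_counts().to_dict()

    analyses: list[AnalysisSpec] = []
    for a in raw.get("analyses", []) or []:
        name = a.get("name", "analysis")
        tissues = a.get("tissues") or sorted(tissues_present)
        merge = a.get("merge", {}) or {}
        threshold = a.get("threshold")
        for t in tissues:
            if t not in tissues_present:
                errors.append(
                    f"analysis {name!r}: tissue {t!r} has no sample in the sheet"
                )
        n_eff = len({merge.get(t, t) for t in tissues})
        if threshold is None:
            errors.append(f"analysis {name!r}: missing entropy threshold")
        elif n_eff > 1 and not 0 < threshold < math.log2(n_eff):
            errors.append(
                f"analysis {name!r}: threshold {threshold} outside "
                f"(0, log2 {n_eff} = {math.log2(n_eff):.3f})"
            )
        analyses.append(AnalysisSpec(name, list(tissues), threshold or 0.0, merge))
    if not analyses and tissues_present:
        n = len(tissues_present)
        default_thr = raw.get("threshold", 3.0)
        if n > 1 and 0 < default_thr < math.log2(n):
            analyses = [AnalysisSpec("all", sorted(tissues_present), default_thr)]
        elif n > 1:
            errors.append(
                f"default threshold {default_thr} outside (0, log2 {n})"
            )

    if errors:
        raise ConfigError(errors)
    outdir = base / raw.get("outdir", "results")
    return PipelineConfig(
        sample_sheet=sheet,
        genome=genome_path,
        tss=tss_path,
        pwms=pwm_path,
        outdir=outdir,
        seed=int(raw.get("seed", 0)),
        proximal_cutoff=int(raw.get("proximal_cutoff", 2000)),
        pseudocount=float(raw.get("pseudocount", 1.0)),
        pwm_threshold_fraction=float(raw.get("pwm_threshold_fraction", 0.6)),
        background_multiple=float(raw.get("background_multiple", 5.0)),
        replicate_mode=str(raw.get("replicate_mode", "reference")),
        analyses=analyses,
        tss_half_width=int(raw.get("tss_half_width", 2000)),
        tss_bin_size=int(raw.get("tss_bin_size", 10)),
        tss_flank=int(raw.get("tss_flank", 100)),
    )
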