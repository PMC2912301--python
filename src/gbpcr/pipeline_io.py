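"""File formats, run configuration, and the end-to-end calling pipeline.

The pipeline consumes three tab-delimited inputs — per-SNP genotype calls, a
segmented log2ratio copy-number profile, and per-SNP heterozygosity priors —
and produces per-chromosome aberration calls:

1. a level mixture is fitted to (or loaded for) the profile's segment levels
   and the continuous-to-discrete interval map is built;
2. a preliminary CN-only classification of every SNP (from its segment mean)
   yields the per-class NoCall rates of the sample, and the emission table's
   NoCall entries are rescaled to the sample's noise level;
3. the per-SNP aberration-class prior is assembled for the configured model
   level and the DP segmentation engine runs chromosome by chromosome;
4. results are written as a BED-compatible segment table, a per-SNP call
   table, and a run-metadata YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cn_prior import (
    CNSegmentProfile,
    LevelMixtureModel,
    build_event_prior_track,
    event_interval_map,
    fit_level_mixture,
)
from .emission_model import (
    HET,
    NHET,
    NOCALL,
    EmissionParamTable,
    NoCallAdjustment,
    adjust_nocall_params,
)
from .errors import ValidationError
from .segmentation_engine import (
    EngineConfig,
    LOHTrack,
    Segment,
    SegmentationResult,
    run_segmentation,
)

logger = logging.getLogger(__name__)

#: Genotype-call dialects collapsed onto the NoCall code.
NOCALL_TOKENS = {"NoCall", "NC", "NN", "---"}
_CALL_MAP = {"AA": NHET, "BB": NHET, "AB": HET, "BA": HET}

EVENT_LABELS = {
    -3: "IBD_UPD",
    -2: "homozygous_deletion",
    -1: "loss",
    0: "normal",
    1: "gain",
    2: "amplification",
}
Y_TOKENS = {NOCALL: "NoCall", HET: "Het", NHET: "NHet"}

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings.

    ``model`` selects the class set (1 = copy-number events only, 2 = adds
    IBD/UPD, 3 = full model with a separate gain class); ``p_upd`` is the
    prior IBD/UPD probability per SNP.  ``mixture`` is either the string
    "fit" (dataset-level weighted EM on the profile's segment levels),
    "reference" (packaged idealized components), or a path to a mixture
    YAML.  ``emission_table`` defaults to the packaged reference table.
    """

    model: int = 3
    p_upd: float = 1e-4
    engine: EngineConfig = field(default_factory=EngineConfig)
    emission_table: str | None = None
    mixture: str = "fit"
    n_mixture_components: int = 3
    adjust_nocall: bool = True
    min_class_size: int = 100
    autosomes_only: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.model not in (1, 2, 3):
            raise ValidationError(f"model must be 1, 2 or 3, got {self.model}")
        if not 0.0 <= self.p_upd <= 1.0:
            raise ValidationError("p_upd must lie in [0, 1]")

    def load_emission_table(self) -> EmissionParamTable:
        if self.emission_table is None:
            return EmissionParamTable.default()
        return EmissionParamTable.from_tsv(self.emission_table)


# ---------------------------------------------------------------------------
# Input parsing
# ---------------------------------------------------------------------------

def _collapse_call(token: str) -> int:
    if token in NOCALL_TOKENS:
        return NOCALL
    try:
        return _CALL_MAP[token]
    except KeyError:
        raise ValidationError(f"unknown genotype token {token!r}") from None


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Genotype TSV (snp_id, chrom, pos, genotype) -> collapsed call codes."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos", "genotype"):
        if col not in df.columns:
            raise ValidationError(f"genotype file {path} lacks column {col!r}")
    df["y"] = [_collapse_call(g) for g in df["genotype"]]
    return df[["snp_id", "chrom", "pos", "y"]]


def read_het_priors(path: str | Path) -> pd.DataFrame:
    """Het-prior TSV (snp_id, het_prior)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    for col in ("snp_id", "het_prior"):
        if col not in df.columns:
            raise ValidationError(f"het-prior file {path} lacks column {col!r}")
    bad = (df["het_prior"] < 0) | (df["het_prior"] > 1)
    if bad.any():
        raise ValidationError(f"het priors outside [0, 1] in {path}")
    return df[["snp_id", "het_prior"]]


def read_cn_profile(path: str | Path) -> pd.DataFrame:
    """Profile TSV (chrom, start_snp_index, end_snp_index, mean_log2ratio, var_log2ratio).

    Indices are 0-based half-open within each chromosome's SNP order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start_snp_index", "end_snp_index", "mean_log2ratio", "var_log2ratio"]
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"CN profile {path} lacks column {col!r}")
    if (df["var_log2ratio"] < 0).any():
        raise ValidationError(f"negative level variances in {path}")
    return df[required]


def read_inputs(
    genotype_path: str | Path,
    cn_profile_path: str | Path,
    het_prior_path: str | Path,
    autosomes_only: bool = True,
    max_dropped_frac: float = 0.1,
) -> tuple[LOHTrack, dict[str, CNSegmentProfile]]:
    """Load and cross-validate the three inputs.

    Profile segment indices refer to the genotype file's per-chromosome SNP
    order.  SNPs missing a het prior are dropped (with a logged count) and
    the profile boundaries are remapped onto the surviving SNPs; a mismatch
    beyond ``max_dropped_frac`` of the SNP set is an error.  Tracks are
    sorted by chromosome then position; each chromosome's profile must tile
    its SNPs without gaps.
    """
    geno = read_genotypes(genotype_path)
    het = read_het_priors(het_prior_path)
    prof = read_cn_profile(cn_profile_path)

    if not geno.sort_values(["chrom", "pos"], kind="stable").equals(geno):
        logger.warning("input SNPs were not sorted; sorting by chromosome and position")
        geno = geno.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    if autosomes_only:
        non_auto = ~geno["chrom"].isin(_AUTOSOMES)
        if non_auto.any():
            logger.info(
                "excluding %d non-autosomal SNPs (pass autosomes_only=False to keep)",
                int(non_auto.sum()),
            )
            geno = geno[~non_auto].reset_index(drop=True)
    if geno.empty:
        raise ValidationError("no SNPs left after filtering")

    merged = geno.merge(het, on="snp_id", how="left")
    missing = merged["het_prior"].isna()
    if missing.any():
        frac = float(missing.mean())
        if frac > max_dropped_frac:
            raise ValidationError(
                f"{int(missing.sum())} of {len(merged)} SNPs ({frac:.1%}) lack a "
                f"het prior (> {max_dropped_frac:.0%} tolerance)"
            )
        logger.warning("dropping %d SNPs without a het prior", int(missing.sum()))

    keep = (~missing).to_numpy()
    kept = merged[keep]
    loh = LOHTrack(
        y=kept["y"].to_numpy(),
        nu=kept["het_prior"].to_numpy(dtype=float),
        chrom=kept["chrom"].to_numpy(),
        pos=kept["pos"].to_numpy(),
        snp_id=kept["snp_id"].to_numpy(),
    )

    profiles: dict[str, CNSegmentProfile] = {}
    chrom_arr = merged["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        n_orig = int(mask.sum())
        rows = prof[prof["chrom"] == chrom].sort_values("start_snp_index")
        if rows.empty:
            raise ValidationError(f"CN profile has no segments for chromosome {chrom}")
        starts = rows["start_snp_index"].to_numpy(dtype=int)
        ends = rows["end_snp_index"].to_numpy(dtype=int)
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]) or ends[-1] != n_orig:
            raise ValidationError(
                f"CN profile does not tile chromosome {chrom}: segments "
                f"{list(zip(starts, ends))} must cover [0, {n_orig}) without gaps"
            )
        # remap boundaries onto surviving SNPs; drop emptied segments
        surv = np.concatenate(([0], np.cumsum(keep[mask])))
        new_ends = surv[ends]
        lengths = np.diff(np.concatenate(([0], new_ends)))
        nonempty = lengths > 0
        profiles[str(chrom)] = CNSegmentProfile(
            boundaries=np.concatenate(([0], new_ends[nonempty])),
            mean=rows["mean_log2ratio"].to_numpy(dtype=float)[nonempty],
            var=rows["var_log2ratio"].to_numpy(dtype=float)[nonempty],
            chrom=str(chrom),
        )
    return loh, profiles


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineResult:
    """Everything the pipeline produced, keyed by chromosome."""

    results: dict[str, SegmentationResult]
    loh: LOHTrack
    params: EmissionParamTable
    mixture: LevelMixtureModel
    adjustment: NoCallAdjustment | None
    config: RunConfig


def _resolve_mixture(
    config: RunConfig, profiles: dict[str, CNSegmentProfile]
) -> LevelMixtureModel:
    if config.mixture == "fit":
        levels = np.concatenate([p.mean for p in profiles.values()])
        lengths = np.concatenate([p.segment_lengths() for p in profiles.values()])
        return fit_level_mixture(
            levels, lengths, n_components=config.n_mixture_components,
            fitted_on="pipeline-profile-levels",
        )
    if config.mixture == "reference":
        return LevelMixtureModel.reference()
    return LevelMixtureModel.from_yaml(config.mixture)


def run_pipeline(
    config: RunConfig,
    loh: LOHTrack,
    profiles: dict[str, CNSegmentProfile],
) -> PipelineResult:
    """Execute the full caller on a loaded sample.

    Deterministic given the config (the EM fit has a fixed initialization
    and the engine is exact); the seed is echoed into the metadata so runs
    remain traceable.
    """
    if loh.chrom is None:
        if len(profiles) != 1:
            raise ValidationError("a track without chromosome labels needs a single profile")
        chrom_arr = np.full(loh.n, next(iter(profiles)))
    else:
        chrom_arr = np.asarray(loh.chrom).astype(str)

    mixture = _resolve_mixture(config, profiles)
    imap = event_interval_map(mixture)
    params = config.load_emission_table()

    # CN-only preliminary classification (gain collapsed onto normal) for the
    # per-class NoCall rates of this sample.
    prelim = np.empty(loh.n, dtype=int)
    for chrom, profile in profiles.items():
        mask = chrom_arr == chrom
        if int(mask.sum()) != profile.n:
            raise ValidationError(
                f"chromosome {chrom}: profile covers {profile.n} SNPs, track has "
                f"{int(mask.sum())}"
            )
        codes = imap.classify(profile.snp_means())
        prelim[mask] = np.where(codes == 1, 0, codes)

    adjustment = None
    if config.adjust_nocall:
        adjustment = NoCallAdjustment.from_sample(
            loh, prelim, params, min_class_size=config.min_class_size
        )
        params = adjust_nocall_params(params, adjustment)

    results: dict[str, SegmentationResult] = {}
    for chrom, profile in profiles.items():
        idx = np.flatnonzero(chrom_arr == chrom)
        sub = loh.slice(int(idx[0]), int(idx[-1]) + 1)
        priors = build_event_prior_track(
            profile, mixture, model=config.model, p_upd=config.p_upd
        )
        try:
            results[chrom] = run_segmentation(
                sub, priors, params, config.engine, chrom=chrom
            )
        except Exception as exc:
            raise type(exc)(f"chromosome {chrom}: {exc}") from exc

    return PipelineResult(
        results=results, loh=loh, params=params, mixture=mixture,
        adjustment=adjustment, config=config,
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def segments_frame(pipeline: PipelineResult) -> pd.DataFrame:
    """Segment table: BED-compatible 0-based half-open bp intervals."""
    chrom_arr = (
        np.asarray(pipeline.loh.chrom).astype(str)
        if pipeline.loh.chrom is not None
        else np.full(pipeline.loh.n, next(iter(pipeline.results)))
    )
    rows = []
    for chrom, result in pipeline.results.items():
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = (
            np.asarray(pipeline.loh.pos)[idx]
            if pipeline.loh.pos is not None
            else np.arange(idx.size)
        )
        for seg in result.segments:
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(pos[seg.start]),
                    "end_bp": int(pos[seg.end - 1]) + 1,
                    "start_snp": seg.start,
                    "end_snp": seg.end,
                    "n_snps": seg.n_snps,
                    "event_code": seg.w,
                    "event_label": EVENT_LABELS[seg.w],
                    "posterior_prob": round(seg.map_prob, 10),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "start_snp", "end_snp", "n_snps",
            "event_code", "event_label", "posterior_prob",
        ],
    )


def per_snp_frame(pipeline: PipelineResult) -> pd.DataFrame:
    """Per-SNP call table: every input SNP exactly once."""
    loh = pipeline.loh
    chrom_arr = (
        np.asarray(loh.chrom).astype(str)
        if loh.chrom is not None
        else np.full(loh.n, next(iter(pipeline.results)))
    )
    frames = []
    for chrom, result in pipeline.results.items():
        idx = np.flatnonzero(chrom_arr == chrom)
        codes = result.per_snp_classes()
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": (
                        np.asarray(loh.snp_id)[idx]
                        if loh.snp_id is not None
                        else [f"snp{j}" for j in idx]
                    ),
                    "chrom": chrom,
                    "pos": (
                        np.asarray(loh.pos)[idx] if loh.pos is not None else idx
                    ),
                    "call": [Y_TOKENS[int(v)] for v in loh.y[idx]],
                    "event_code": codes,
                    "event_label": [EVENT_LABELS[int(c)] for c in codes],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_results(pipeline: PipelineResult, out_prefix: str | Path) -> dict[str, Path]:
    """Write the segment table, the per-SNP table, and the run metadata."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    seg_path = prefix.with_name(prefix.name + ".segments.tsv")
    snp_path = prefix.with_name(prefix.name + ".snps.tsv")
    meta_path = prefix.with_name(prefix.name + ".meta.yaml")

    segments_frame(pipeline).to_csv(seg_path, sep="\t", index=False)
    per_snp_frame(pipeline).to_csv(snp_path, sep="\t", index=False)

    cfg = asdict(pipeline.config)
    cfg["engine"]["thresholds"] = asdict(pipeline.config.engine.thresholds)
    meta = {
        "gbpcr_version": __version__,
        "seed": pipeline.config.seed,
        "config": cfg,
        "emission_table_adjusted": bool(pipeline.params.adjusted),
        "nocall_rates": None
        if pipeline.adjustment is None
        else {
            "r1": {int(z): float(r) for z, r in pipeline.adjustment.r1.items()},
            "r2": {int(z): float(r) for z, r in pipeline.adjustment.r2.items()},
        },
        "mixture": {
            "fitted_on": pipeline.mixture.fitted_on,
            "components": [
                {"label": l, "weight": float(w), "mean": float(m), "sd": float(s)}
                for l, w, m, s in zip(
                    pipeline.mixture.labels, pipeline.mixture.weights,
                    pipeline.mixture.means, pipeline.mixture.sds,
                )
            ],
        },
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return {"segments": seg_path, "snps": snp_path, "meta": meta_path}


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read back a segment table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
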