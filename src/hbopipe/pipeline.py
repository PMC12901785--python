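"""End-to-end pipeline runner on synthetic or file inputs.

A full synthetic run emulates the study design: four experimental groups
(mock/propofol at 60 and 90 days in vitro), eight organoids per group on
the MEA arm, five RNA samples per group.  Per organoid the signal chain is
recalibration excision -> flash removal -> bandpass -> spike detection ->
top-channel selection -> activity summary; the transcriptomic chain is
expression filtering -> DEG calling per contrast -> list overlaps
(representation factors) -> over-representation and pre-ranked enrichment.
All randomness derives from one seed; results are bit-reproducible and
every table carries the configuration hash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hbopipe import deg as _deg
from hbopipe import genesets as _gs
from hbopipe import mea_signal as _ms
from hbopipe import spikes as _sp
from hbopipe import synthdata as _syn
from hbopipe.config import PipelineConfig
from hbopipe.io import activity_to_frame

# per-group mean firing rates (Hz) of the emulated study conditions:
# maturation raises activity from 60 to 90 div, and treatment raises it at
# 60 div only; two 90-div mock organoids are inactive
SIM_GROUP_RATES = {"mock_60": 1.0, "prop_60": 2.0, "mock_90": 2.5, "prop_90": 2.5}
SIM_INACTIVE = {"mock_90": 2}   # organoids with near-zero activity
SIM_INACTIVE_RATE = 0.02        # Hz


@dataclass
class PipelineResult:
    config_hash: str
    activity: pd.DataFrame
    group_comparison: pd.DataFrame
    deg_tables: dict[str, pd.DataFrame]
    overlaps: pd.DataFrame
    enrichment: pd.DataFrame | None
    gsea: pd.DataFrame | None
    log: dict = field(default_factory=dict)


def analyze_recording(rec, cfg: PipelineConfig, taps=None) -> _sp.OrganoidActivity:
    """Signal chain for one organoid recording."""
    mask = _ms.excise_recalibration(rec, border=cfg.excision_border)
    mask = _ms.detect_flashes(
        rec, mask=mask, saturation_frac=cfg.saturation_frac,
        channel_frac=cfg.flash_channel_frac, pad=cfg.flash_pad,
    )
    if taps is None:
        taps = _ms.design_bandpass(rec.fs, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_numtaps)
    activities = []
    for ch in range(rec.n_channels):
        filt = _ms.bandpass_filter_masked(rec.samples[ch], mask, rec.fs, taps=taps)
        train = _sp.detect_spikes(
            filt, mask, rec.fs, channel_id=int(rec.channel_ids[ch]),
            window_ms=cfg.detect_window_ms, k=cfg.detect_k,
            refractory_ms=cfg.refractory_ms,
        )
        activities.append(_sp.channel_frequency(train, mask))
    selection = _sp.select_channels(activities, top_n=cfg.top_n_channels, max_hz=cfg.max_channel_hz)
    return _sp.organoid_summary(
        selection, organoid_id=str(rec.metadata.get("organoid_id", "")),
        min_mean_hz=cfg.min_mean_hz,
    )


def simulate_mea_study(cfg: PipelineConfig) -> pd.DataFrame:
    """Generate and analyze the full synthetic MEA arm.

    Returns the per-organoid activity table (organoid, group, mean rate,
    included flag).
    """
    ss = np.random.SeedSequence(cfg.seed)
    taps = _ms.design_bandpass(cfg.fs, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_numtaps)
    rows = []
    child_seeds = ss.spawn(4 * cfg.sim_n_organoids_per_group)
    i = 0
    for group in _syn.GROUPS_DEFAULT:
        n_inactive = SIM_INACTIVE.get(group, 0)
        for k in range(cfg.sim_n_organoids_per_group):
            seed = int(child_seeds[i].generate_state(1)[0] % (2**31)); i += 1
            inactive = k >= cfg.sim_n_organoids_per_group - n_inactive
            base = SIM_INACTIVE_RATE if inactive else SIM_GROUP_RATES[group] * cfg.sim_rate_hz / 2.0
            # mild organoid-to-organoid rate heterogeneity
            jitter = np.random.default_rng(seed).lognormal(mean=0.0, sigma=0.15)
            # every simulated channel is an active site: the study keeps the
            # top-30 most active channels of a dense array, which are the
            # firing ones, and simulating thousands of silent sites would
            # only dilute the emulated organoid mean
            mea_cfg = _syn.MeaSimConfig(
                n_channels=cfg.sim_n_channels, fs=cfg.fs, duration=cfg.sim_duration_s,
                rate_hz=base * jitter, active_fraction=1.0, seed=seed,
            )
            rec, _truth = _syn.generate_mea_recording(mea_cfg)
            rec.metadata["organoid_id"] = f"{group}_o{k+1}"
            summary = analyze_recording(rec, cfg, taps=taps)
            rows.append((summary.organoid_id, group, summary.mean_frequency_hz, summary.included))
    return pd.DataFrame(rows, columns=["organoid", "group", "mean_freq_hz", "included"])


def compare_activity(activity: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA + Šídák pairwise comparisons over included organoids."""
    from hbopipe.stats import GroupSample, anova_sidak

    kept = activity[activity["included"]]
    groups = [
        GroupSample(label=g, values=kept.loc[kept["group"] == g, "mean_freq_hz"].to_numpy())
        for g in kept["group"].unique()
    ]
    omnibus, pairwise = anova_sidak(groups)
    rows = [("omnibus_F", "", omnibus.statistic, omnibus.p, np.nan)]
    for r in pairwise:
        rows.append((r.comparison[0], r.comparison[1], r.statistic, r.p, r.p_adjusted))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "p_adjusted"])


CONTRASTS = {
    "maturation": ("mock_90", "mock_60"),
    "treatment_60": ("prop_60", "mock_60"),
    "treatment_90": ("prop_90", "mock_90"),
}


def run_transcriptomics(cfg: PipelineConfig, collection: _gs.GeneSetCollection | None = None):
    """Transcriptomic arm on a synthetic matrix; returns tables + the truth."""
    expr_cfg = _syn.ExprSimConfig(n_genes=cfg.sim_n_genes, seed=cfg.seed)
    matrix, truth = _syn.generate_expression_matrix(expr_cfg)
    filtered = _deg.filter_low_expression(matrix, cfg.expr_min_valid, cfg.expr_min_value)

    deg_tables = {
        name: _deg.call_degs(filtered, a, b, cfg.deg_min_diff, cfg.deg_min_fc, cfg.deg_alpha)
        for name, (a, b) in CONTRASTS.items()
    }
    lists = {name: _deg.deg_lists(t) for name, t in deg_tables.items()}
    n_bg = filtered.n_genes

    overlap_rows = []
    pairs = [
        ("maturation_up_vs_treatment60_up", lists["maturation"][0], lists["treatment_60"][0]),
        ("maturation_up_vs_treatment90_up", lists["maturation"][0], lists["treatment_90"][0]),
        ("maturation_down_vs_treatment90_down", lists["maturation"][1], lists["treatment_90"][1]),
    ]
    for name, l1, l2 in pairs:
        if not l1 or not l2:
            continue
        x = len(set(l1) & set(l2))
        r = _gs.representation_factor(x, len(l1), len(l2), n_bg)
        overlap_rows.append((name, r.n1, r.n2, r.x, r.N, r.rf, r.p))
    overlaps = pd.DataFrame(
        overlap_rows, columns=["comparison", "n1", "n2", "x", "N", "rf", "p"]
    )

    enrichment = gsea = None
    if collection is None:
        collection = synthetic_gene_sets(filtered.values.index.tolist(), truth, seed=cfg.seed)
    up_mat = lists["maturation"][0]
    if up_mat:
        enrichment = _gs.hypergeom_enrichment(
            up_mat, filtered.values.index.tolist(), collection
        )
    ranked = _gs.rank_genes(deg_tables["maturation"])
    gsea = _gs.preranked_gsea(ranked, collection, n_perm=cfg.gsea_n_perm, seed=cfg.seed)
    return matrix, truth, filtered, deg_tables, overlaps, enrichment, gsea


def synthetic_gene_sets(
    genes: list[str], truth: _syn.ExprTruth, seed: int = 0,
    n_random: int = 25, set_size: int = 60,
) -> _gs.GeneSetCollection:
    """A small GMT-style collection for synthetic runs: one set planted in
    the maturation-up program plus random same-size sets."""
    rng = np.random.default_rng(seed)
    gene_arr = np.asarray(genes)
    sets = {}
    mat_up = [g for g in truth.maturation.index[truth.maturation > 0] if g in set(genes)]
    if len(mat_up) >= 5:
        take = min(set_size, len(mat_up))
        planted = list(rng.choice(mat_up, size=take, replace=False))
        if take < set_size:
            planted += list(rng.choice(gene_arr, size=set_size - take, replace=False))
        sets["MATURATION_PROGRAM"] = set(planted)
    for i in range(n_random):
        sets[f"RANDOM_{i:03d}"] = set(rng.choice(gene_arr, size=set_size, replace=False))
    return _gs.GeneSetCollection(sets=sets, category="synthetic")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Full synthetic run of both arms; optionally writes all tables."""
    cfg.validate()
    chash = cfg.hash()
    activity = simulate_mea_study(cfg)
    comparison = compare_activity(activity)
    matrix, truth, filtered, deg_tables, overlaps, enrichment, gsea = run_transcriptomics(cfg)

    log = {
        "config_hash": chash,
        "n_organoids": int(len(activity)),
        "n_included": int(activity["included"].sum()),
        "retention_pct": 100.0 * float(activity["included"].mean()),
        "n_genes_input": int(matrix.n_genes),
        "n_genes_filtered": int(filtered.n_genes),
        "deg_counts": {
            name: {
                "up": int((t["deg_class"] == "up").sum()),
                "down": int((t["deg_class"] == "down").sum()),
            }
            for name, t in deg_tables.items()
        },
    }
    result = PipelineResult(
        config_hash=chash, activity=activity, group_comparison=comparison,
        deg_tables=deg_tables, overlaps=overlaps, enrichment=enrichment,
        gsea=gsea, log=log,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write(activity, outdir / "activity.csv", chash)
        _write(comparison, outdir / "group_comparison.csv", chash)
        for name, t in deg_tables.items():
            _write(t, outdir / f"degs_{name}.csv", chash, index=True)
        _write(overlaps, outdir / "overlaps.csv", chash)
        if enrichment is not None:
            _write(enrichment, outdir / "enrichment.csv", chash, index=True)
        if gsea is not None:
            _write(gsea, outdir / "gsea.csv", chash, index=True)
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return result


def _write(df: pd.DataFrame, path: Path, chash: str, index: bool = False):
    with open(path, "w") as f:
        f.write(f"# config_hash={chash}\n")
        df.to_csv(f, index=index)
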