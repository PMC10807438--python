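"""End-to-end pipeline orchestration and input validation.

``run_pipeline`` executes whichever stages have inputs configured —
plate correction and niche scoring, functional and phylogenetic distance
matrices, antagonism statistics, growth fitting, supernatant summaries —
and writes tidy per-stage outputs plus a machine-readable ``summary.json``
holding every headline statistic.  Runs are deterministic given the inputs
and seed; every run writes a ``manifest.json`` with the config hash, seed
and software version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, metabolic, phylo, plates as pl, stats, growth as gr
from .ecoplate import DAYS, REPLICATES, WATER

log = logging.getLogger("microniche")


@dataclass
class RunConfig:
    """Paths and analysis options for a pipeline run.

    Any input path may be None; the corresponding stage is skipped.
    """

    plate_csv: str | None = None
    node_sets_tsv: str | None = None
    alignment_fasta: str | None = None
    inhibition_csv: str | None = None
    growth_csv: str | None = None
    supernatant_csv: str | None = None
    out_dir: str = "microniche_out"
    day: int = 7
    expansion_variant: str = "printed"
    quantile_method: str = "linear"
    blank_pool: str = "global"
    alpha: float = 0.05
    mcnemar_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.day not in (4, 7):
            raise ValueError("niche-call day must be 4 or 7")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    niche_frame = None
    if config.plate_csv:
        try:
            raw = io.read_plate_csv(config.plate_csv)
            corrected = pl.correct_absorbance(raw)
            niche_frame = pl.score_growth(
                corrected, day=config.day,
                quantile_method=config.quantile_method,
                blank_pool=config.blank_pool,
            )
            results = pl.pair_niche_results(niche_frame, config.expansion_variant)
            niche_frame.to_csv(out / "niche_calls.csv")
            pl.pair_results_frame(results).to_csv(
                out / "pair_niche.tsv", sep="\t", index=False
            )
            deformation = pl.summarize_deformation(results) if results else None
            summary["niche"] = {"n_cultures": int(niche_frame.shape[0])}
            if deformation:
                summary["niche"]["deformation"] = deformation
                xs = [r.overlap_index for r in results]
                ys = [float(r.expansion_count) for r in results]
                try:
                    pe = stats.pearson_corr(xs, ys)
                    summary["niche"]["expansion_vs_overlap"] = {
                        "r": pe.r, "r_squared": pe.r_squared,
                        "p": pe.p_two_sided, "n": pe.n,
                    }
                except ValueError as exc:
                    summary["niche"]["expansion_vs_overlap"] = {"note": str(exc)}
            log.info("niche stage: %d cultures scored", niche_frame.shape[0])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("niche", str(exc)) from exc

    func_matrix = None
    if config.node_sets_tsv:
        try:
            node_sets = io.read_node_sets_tsv(config.node_sets_tsv)
            func_matrix = metabolic.functional_distance_matrix(node_sets)
            io.write_matrix_csv(func_matrix, out / "functional_distance.csv")
            off = func_matrix.to_numpy()[np.triu_indices(len(func_matrix), 1)]
            summary["functional_distance"] = {
                "n_strains": len(func_matrix),
                "n_pairs": int(off.size),
                "mean": float(off.mean()),
            }
        except Exception as exc:
            raise StageError("functional_distance", str(exc)) from exc

    phylo_matrix = None
    if config.alignment_fasta:
        try:
            seqs = io.read_alignment_fasta(config.alignment_fasta)
            tn = phylo.tajima_nei_matrix(seqs)
            io.write_matrix_csv(tn, out / "tajima_nei.csv")
            if np.isnan(tn.to_numpy()).any():
                raise ValueError("saturated (undefined) Tajima-Nei cells; "
                                 "cannot build an NJ tree")
            newick = phylo.neighbor_joining(tn)
            (out / "nj_tree.nwk").write_text(newick + "\n")
            phylo_matrix = phylo.patristic(newick)
            io.write_matrix_csv(phylo_matrix, out / "patristic.csv")
            off = phylo_matrix.to_numpy()[np.triu_indices(len(phylo_matrix), 1)]
            summary["phylogenetic_distance"] = {
                "n_strains": len(phylo_matrix),
                "n_pairs": int(off.size),
                "mean_patristic": float(off.mean()),
            }
        except Exception as exc:
            raise StageError("phylogenetic_distance", str(exc)) from exc

    if config.inhibition_csv:
        try:
            records = io.read_inhibition_csv(config.inhibition_csv)
            pair_labels = stats.pair_inhibition(records)
            pair_labels.to_csv(out / "pair_inhibition.tsv", sep="\t", index=False)
            inh = {"levels": {}}
            labels_by_level = {}
            for level, grp in pair_labels[~pair_labels["is_self"]].groupby(
                "resource_level"
            ):
                grp = grp.sort_values(["strain_i", "strain_j"])
                labels_by_level[level] = grp
                inh["levels"][level] = {
                    "n_pairs": int(len(grp)),
                    "n_antagonistic": int(grp["antagonistic"].sum()),
                }
            if len(labels_by_level) == 2 and {"high", "low"} <= set(labels_by_level):
                h = labels_by_level["high"]["antagonistic"].to_numpy()
                l = labels_by_level["low"]["antagonistic"].to_numpy()
                try:
                    mc = stats.mcnemar_paired(h, l, config.mcnemar_correction)
                    inh["mcnemar"] = {
                        "chi2": mc.chi2, "df": mc.df,
                        "p_one_sided": mc.p_one_sided, "b": mc.b, "c": mc.c,
                    }
                except ValueError as exc:
                    inh["mcnemar"] = {"note": str(exc)}
            for dist_name, matrix in (
                ("patristic", phylo_matrix), ("functional", func_matrix)
            ):
                if matrix is None:
                    continue
                fits = {}
                for level, grp in labels_by_level.items():
                    d = [
                        matrix.loc[i, j]
                        for i, j in zip(grp["strain_i"], grp["strain_j"])
                    ]
                    try:
                        fit = stats.fit_inhibition_glm(
                            grp["antagonistic"].to_numpy(), d
                        )
                        fits[level] = {
                            "intercept": fit.intercept, "slope": fit.slope,
                            "p_slope": fit.p_slope, "pseudo_r2": fit.pseudo_r2,
                            "n": fit.n,
                        }
                    except (stats.SeparationError, ValueError) as exc:
                        fits[level] = {"note": str(exc)}
                inh[f"glm_vs_{dist_name}"] = fits
                if (
                    {"high", "low"} <= set(fits)
                    and "slope" in fits["high"] and "slope" in fits["low"]
                ):
                    fit_h = stats.GlmFit(
                        fits["high"]["intercept"], fits["high"]["slope"],
                        0, 0, 0, 0, 0, 1, 1, fits["high"]["n"], (0.0, 1.0),
                    )
                    fit_l = stats.GlmFit(
                        fits["low"]["intercept"], fits["low"]["slope"],
                        0, 0, 0, 0, 0, 1, 1, fits["low"]["n"], (0.0, 1.0),
                    )
                    try:
                        x_star, _ = stats.logistic_curve_intersection(fit_h, fit_l)
                        inh[f"glm_vs_{dist_name}"]["intersection"] = x_star
                    except ValueError:
                        pass
            summary["inhibition"] = inh
        except StageError:
            raise
        except Exception as exc:
            raise StageError("inhibition", str(exc)) from exc

    if config.growth_csv:
        try:
            series = io.read_growth_csv(config.growth_csv)
            fits = gr.fit_growth_table(series)
            fits.to_csv(out / "growth_fits.tsv", sep="\t", index=False)
            summary["growth"] = {
                "n_series": int(len(fits)),
                "n_converged": int(fits["converged"].sum()),
                "mean_r": float(fits["r"].mean()),
            }
        except Exception as exc:
            raise StageError("growth", str(exc)) from exc

    if config.supernatant_csv:
        try:
            table = io.read_supernatant_csv(config.supernatant_csv)
            cases = gr.spent_ratio_table(table, alpha=config.alpha)
            pd.DataFrame(
                [
                    {
                        "grower": c.grower_id, "donor": c.donor_id,
                        "resource_level": c.resource_level,
                        "log_ratio": c.log_ratio,
                        "classification": c.classification,
                    }
                    for c in cases
                ]
            ).to_csv(out / "supernatant_cases.tsv", sep="\t", index=False)
            summary["supernatant"] = gr.facilitation_summary(cases, alpha=config.alpha)
        except Exception as exc:
            raise StageError("supernatant", str(exc)) from exc

    summary = _round_floats(summary)
    io.write_json(summary, out / "summary.json")
    io.write_json(
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "config": _round_floats(asdict(config)),
        },
        out / "manifest.json",
    )
    return summary


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(config: RunConfig) -> list[str]:
    """Schema checks for each configured input; returns a list of issues
    (empty for a well-formed bundle).  Report-only: never raises for a
    content problem."""
    issues: list[str] = []

    def check(path, reader, checks):
        if path is None:
            return
        if not Path(path).exists():
            issues.append(f"{path}: file not found")
            return
        try:
            obj = reader(path)
        except Exception as exc:
            issues.append(f"{path}: {exc}")
            return
        checks(obj)

    def plate_checks(df: pd.DataFrame) -> None:
        ctx = pl._with_context(df)
        if not np.isfinite(df["absorbance"]).all():
            issues.append(f"{config.plate_csv}: non-finite absorbance values")
        bad_days = sorted(set(df["day"]) - set(DAYS))
        if bad_days:
            issues.append(f"{config.plate_csv}: unexpected days {bad_days}")
        for context, grp in ctx.groupby("context"):
            if 0 not in set(grp["day"]):
                rows = grp.index[:3].tolist()
                issues.append(
                    f"{config.plate_csv}: context {context} has no day-0 rows "
                    f"(e.g. rows {rows})"
                )
            if WATER not in set(grp["source"]):
                issues.append(
                    f"{config.plate_csv}: context {context} has no water blanks"
                )
            reps = grp.groupby(["source", "day"])["replicate"].nunique()
            if (reps != len(REPLICATES)).any():
                bad = reps[reps != len(REPLICATES)].index[:2].tolist()
                issues.append(
                    f"{config.plate_csv}: context {context} has replicate counts "
                    f"!= {len(REPLICATES)} for {bad}"
                )

    def alignment_checks(seqs: dict[str, str]) -> None:
        pass  # length equality enforced by the reader

    def inhibition_checks(df: pd.DataFrame) -> None:
        if not set(df["halo"].unique()) <= {0, 1}:
            issues.append(f"{config.inhibition_csv}: halo values outside 0/1")

    check(config.plate_csv, io.read_plate_csv, plate_checks)
    check(config.node_sets_tsv, io.read_node_sets_tsv, lambda o: None)
    check(config.alignment_fasta, io.read_alignment_fasta, alignment_checks)
    check(config.inhibition_csv, io.read_inhibition_csv, inhibition_checks)
    check(config.growth_csv, io.read_growth_csv, lambda o: None)
    check(config.supernatant_csv, io.read_supernatant_csv, lambda o: None)
    return issues
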