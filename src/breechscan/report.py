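"""End-to-end analysis orchestration and report assembly.

``run_full_analysis`` executes the whole pipeline — read records, apply
exclusions, the per-outcome planned-cesarean rule, epoch summaries,
descriptive comparisons, Bayesian risk-ratio fits (informative prior where
supplied, plus the weakly-informative sensitivity fit), number needed to
scan, and the interrupted time series — and writes one JSON/TSV artifact per
stage plus a run log.  Every numeric cell in the outcome table is
re-derivable from the per-stage artifacts, and all randomness flows from the
single config seed (one spawned sub-seed per Bayesian fit).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .bayes import (
    MCMCConfig,
    RRPrior,
    elicit_normal_prior,
    fit_logbinomial,
    number_needed_to_scan,
    sensitivity_flat,
    zero_event_correction,
)
from .cohort import (
    KNOWN_OUTCOMES,
    BirthRecord,
    EpochSpec,
    apply_exclusions,
    apply_planned_cs_rule,
    read_birth_records,
    summarise,
)
from .descriptives import compare_continuous, compare_proportions
from .its import aggregate_monthly, fit_its

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    denominator: str = "breech_births"
    prior: Mapping | None = None  # {"rr","ci_low","ci_high"} or {"mu","sigma"}

    def build_prior(self) -> RRPrior | None:
        if self.prior is None:
            return None
        spec = dict(self.prior)
        if "rr" in spec:
            return elicit_normal_prior(spec["rr"], spec["ci_low"], spec["ci_high"])
        return RRPrior(mu=spec["mu"], sigma=spec["sigma"], flavour="informative")


@dataclass(frozen=True)
class AnalysisConfig:
    input_path: str
    cut_date: dt.date
    outcomes: tuple[OutcomeSpec, ...]
    output_dir: str
    seed: int = 0
    mcmc_iter: int = 1500
    mcmc_burnin: int = 500
    mcmc_chains: int = 2
    its_spline_df: int = 4
    its_family: str = "gaussian"

    def __post_init__(self) -> None:
        for spec in self.outcomes:
            if spec.name not in KNOWN_OUTCOMES:
                raise ValueError(
                    f"unknown outcome {spec.name!r}; known: {sorted(KNOWN_OUTCOMES)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        outcomes = tuple(
            OutcomeSpec(
                name=o["name"],
                denominator=o.get("denominator", "breech_births"),
                prior=o.get("prior"),
            )
            for o in raw["outcomes"]
        )
        return cls(
            input_path=raw["input_path"],
            cut_date=dt.date.fromisoformat(str(raw["cut_date"])),
            outcomes=outcomes,
            output_dir=raw["output_dir"],
            seed=int(raw.get("seed", 0)),
            mcmc_iter=int(raw.get("mcmc_iter", 1500)),
            mcmc_burnin=int(raw.get("mcmc_burnin", 500)),
            mcmc_chains=int(raw.get("mcmc_chains", 2)),
            its_spline_df=int(raw.get("its_spline_df", 4)),
            its_family=raw.get("its_family", "gaussian"),
        )


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _fmt_fit(fit) -> str:
    return (
        f"{fit.rr_median:.2f} ({fit.cri_low:.2f}, {fit.cri_high:.2f})"
    )


def run_full_analysis(
    config: AnalysisConfig, records: Sequence[BirthRecord] | None = None
) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    ``records`` may be supplied directly (bypassing the CSV read) for
    programmatic use.  On any stage failure the partially written outputs
    are removed and :class:`StageError` is raised naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    epoch = EpochSpec(cut_date=config.cut_date)
    seed_seq = np.random.SeedSequence(config.seed)
    bundle: dict = {"seed": config.seed, "warnings": []}

    def emit(name: str, payload) -> None:
        path = outdir / name
        _write_json(path, payload)
        written.append(path)

    try:
        stage = "read"
        if records is None:
            records = read_birth_records(config.input_path)
        records = list(records)

        stage = "exclusions"
        kept, tally = apply_exclusions(records)
        bundle["exclusions"] = dict(tally)
        bundle["n_input"] = len(records)
        bundle["n_analysed"] = len(kept)
        emit("exclusions.json", {"input": len(records), "kept": len(kept),
                                 "tally": dict(tally)})

        stage = "descriptives"
        before = [r for r in kept if not epoch.is_after(r.birth_date)]
        after = [r for r in kept if epoch.is_after(r.birth_date)]
        if not before or not after:
            raise ValueError("one of the epochs contains no records")
        rows = []
        for attr, label in [("maternal_age_years", "maternal_age"), ("bmi", "bmi")]:
            x = [getattr(r, attr) for r in before if not math.isnan(getattr(r, attr))]
            y = [getattr(r, attr) for r in after if not math.isnan(getattr(r, attr))]
            if x and y:
                rows.append(compare_continuous(x, y, "welch_t", variable=label))
        rows.append(
            compare_proportions(
                sum(r.parous for r in before), len(before),
                sum(r.parous for r in after), len(after),
                variable="parous",
            )
        )
        breech_b = sum(r.presentation_at_birth == "breech" for r in before)
        breech_a = sum(r.presentation_at_birth == "breech" for r in after)
        rows.append(
            compare_proportions(
                breech_b, len(before), breech_a, len(after), variable="breech"
            )
        )
        desc_path = outdir / "descriptives.tsv"
        with open(desc_path, "w", encoding="utf-8") as handle:
            handle.write("variable\tbefore\tafter\ttest\tstatistic\tp_value\n")
            for row in rows:
                handle.write(
                    f"{row.variable}\t{row.summary_before}\t{row.summary_after}"
                    f"\t{row.test_name}\t{row.statistic:.6g}\t{row.p_value:.6g}\n"
                )
        written.append(desc_path)

        stage = "bayes"
        mcmc_base = dict(
            n_chains=config.mcmc_chains,
            n_iter=config.mcmc_iter,
            n_burnin=config.mcmc_burnin,
        )
        outcome_rows = []
        bundle["outcomes"] = {}
        for spec in config.outcomes:
            pool = apply_planned_cs_rule(kept, spec.name)
            summary = summarise(pool, epoch, spec.name, denominator=spec.denominator)
            corrected = zero_event_correction(summary)
            sub_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            mcmc = MCMCConfig(seed=sub_seed, **mcmc_base)
            flat_fit = sensitivity_flat(corrected, mcmc)
            prior = spec.build_prior()
            info_fit = (
                fit_logbinomial(corrected, prior, mcmc) if prior is not None else None
            )
            entry = {
                "summary": summary.to_dict(),
                "zero_corrected": corrected.zero_corrected,
                "flat": flat_fit.to_dict(),
                "informative": info_fit.to_dict() if info_fit else None,
            }
            bundle["outcomes"][spec.name] = entry
            bundle["warnings"].extend(
                f"{spec.name}: {w}" for w in flat_fit.warnings
            )
            if info_fit:
                bundle["warnings"].extend(
                    f"{spec.name} (informative): {w}" for w in info_fit.warnings
                )
            a, c = summary.events
            n1, n2 = summary.totals
            p1, p2 = summary.percentages
            outcome_rows.append(
                f"{spec.name}\t{a} ({p1:.1f})\t{c} ({p2:.1f})"
                f"\t{_fmt_fit(flat_fit)}\t{100 * flat_fit.prob_reduction:.1f}%"
                + (
                    f"\t{_fmt_fit(info_fit)}\t{100 * info_fit.prob_reduction:.1f}%"
                    if info_fit
                    else "\tNE\t–"
                )
            )
        emit("bayes.json", bundle["outcomes"])
        table_path = outdir / "outcome_table.tsv"
        with open(table_path, "w", encoding="utf-8") as handle:
            handle.write(
                "outcome\tbefore_n_pct\tafter_n_pct\trr_flat\tprob_reduction_flat"
                "\trr_informative\tprob_reduction_informative\n"
            )
            handle.write("\n".join(outcome_rows) + "\n")
        written.append(table_path)

        stage = "nns"
        nns_payload = None
        if any(s.name == "undiagnosed_breech" for s in config.outcomes):
            pool = apply_planned_cs_rule(kept, "undiagnosed_breech")
            pop_summary = summarise(
                pool, epoch, "undiagnosed_breech", denominator="all_births"
            )
            try:
                nns, (lo, hi) = number_needed_to_scan(pop_summary)
                nns_payload = {
                    "nns": nns,
                    "ci": [lo, hi if math.isfinite(hi) else None],
                    "counts": pop_summary.to_dict(),
                }
            except ValueError as exc:
                nns_payload = {"nns": None, "reason": str(exc)}
            emit("nns.json", nns_payload)
        bundle["nns"] = nns_payload

        stage = "its"
        breech_records = [
            r for r in apply_planned_cs_rule(kept, "undiagnosed_breech")
            if r.presentation_at_birth == "breech"
        ]
        series = aggregate_monthly(breech_records, epoch)
        its_result = fit_its(
            series, spline_df=config.its_spline_df, family=config.its_family
        )
        bundle["its"] = its_result.to_dict()
        emit("its.json", {
            "months": list(series.months),
            "counts": [int(v) for v in series.counts],
            "exposure": [int(v) for v in series.exposure],
            **its_result.to_dict(),
        })

        stage = "runlog"
        emit("runlog.json", {
            "seed": config.seed,
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "warnings": bundle["warnings"],
        })
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    return bundle
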