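"""End-to-end orchestration: simulate, call and evaluate.

The calling pipeline runs the stages in their natural order — public
cleaning, index cleaning, pair collapsing, discriminating-position
selection, signature assignment, per-amplicon pileup and calling — and
logs stage-level counters to the :mod:`logging` channel ``ampvar``.

Index cleaning needs to know the sample index and the target length.
When the panel shares one index across amplicons the R2 prefix trim runs
globally before collapsing; R1 truncation, which depends on the target
length, runs globally only when all targets share one length.  Panels
with heterogeneous short targets should pre-trim reads or accept the
residual adapter, which the alignment acceptance gate rejects anyway.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import pandas as pd
import yaml

from .io_formats import (
    AmpliconPanel,
    VariantRecord,
    load_panel,
    read_fastq_pair,
    read_variants,
    write_variants,
)
from .pair_collapse import collapse
from .primer_features import select_positions
from .read_assignment import assign
from .read_cleaning import clean_public, trim_index_prefix, truncate_r1
from .simulation_eval import (
    match_calls,
    random_panel,
    random_truth,
    read_truth,
    recall,
    simulate_reads,
    tpr_fpr_accuracy,
)
from .variant_calling import CallingThresholds, call_amplicon

__all__ = ["PipelineConfig", "run_call", "run_simulate", "run_evaluate"]

logger = logging.getLogger("ampvar")


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline with its conventional default.

    ``phi`` = 1 keeps all collapsed sequences; ``epsilon`` = None uses
    the automatic ``|m - n| + 1`` band widened by ``max_indel`` to absorb
    indel-shifted diagonals; the 0.90 reference-fraction threshold, the
    ``k_max`` = 2 acceptance gate and the 3-substitution index-match
    budget are the method's standard settings.
    """

    phi: int = 1
    epsilon: int | None = None
    max_indel: int = 10
    snp_ref_fraction: float = 0.90
    k_max: int = 2
    min_depth: int = 10
    index_max_mismatch: int = 3
    rescue_assignment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phi < 1:
            raise ValueError("phi must be >= 1")
        if self.index_max_mismatch < 0:
            raise ValueError("index_max_mismatch must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> CallingThresholds:
        return CallingThresholds(
            snp_ref_fraction=self.snp_ref_fraction,
            k_max=self.k_max,
            min_depth=self.min_depth,
            max_indel=self.max_indel,
            epsilon=self.epsilon,
        )


def _as_panel(panel) -> AmpliconPanel:
    return panel if isinstance(panel, AmpliconPanel) else load_panel(panel)


def run_call(
    r1_path,
    r2_path,
    panel,
    config: PipelineConfig | None = None,
    out_vcf=None,
    out_report=None,
) -> tuple[list[VariantRecord], dict]:
    """Run the full calling pipeline on one FASTQ pair.

    Returns the call list and a report dictionary of stage counters;
    optionally writes the VCF and a two-column TSV report.
    """
    config = config or PipelineConfig()
    panel = _as_panel(panel)
    logger.info("config: %s", asdict(config))

    pairs = list(read_fastq_pair(r1_path, r2_path))
    pairs, cleaning = clean_public(pairs, panel.public_seq)
    logger.info(
        "public cleaning: %d in, %d dropped, %d surviving",
        cleaning.input_pairs, cleaning.dropped_public, cleaning.surviving_pairs,
    )

    shared_index = panel.shared_index
    if shared_index is not None:
        pairs, n_trimmed = trim_index_prefix(
            pairs, shared_index, config.index_max_mismatch
        )
        cleaning.index_trimmed = n_trimmed
        logger.info("index cleaning: %d R2 prefixes trimmed", n_trimmed)
    else:
        logger.warning(
            "amplicons use different index sequences; skipping global "
            "index trim"
        )
    uniform_len = panel.uniform_target_length
    if uniform_len is not None and uniform_len < 150:
        pairs, n_truncated = truncate_r1(pairs, uniform_len)
        cleaning.r1_truncated = n_truncated
        logger.info("index cleaning: %d R1 reads truncated", n_truncated)

    collapsed = collapse(pairs, phi=config.phi)
    n_retained = sum(c.frequency for c in collapsed)
    logger.info(
        "collapse: %d distinct sequences retained at phi=%d "
        "(%d of %d pairs represented)",
        len(collapsed), config.phi, n_retained, cleaning.surviving_pairs,
    )

    catalog = select_positions(panel)
    logger.info(
        "feature catalog: positions %s over %d amplicons",
        list(catalog.selected_positions), len(panel),
    )
    assigned = assign(
        collapsed,
        catalog,
        rescue=config.rescue_assignment,
        panel=panel,
        k_max=config.k_max,
    )
    n_unassigned = sum(1 for a in assigned if a.amplicon_id is None)
    unassigned_mass = sum(
        a.collapsed.frequency for a in assigned if a.amplicon_id is None
    )
    logger.info(
        "assignment: %d/%d sequences unassigned (%d pairs)",
        n_unassigned, len(assigned), unassigned_mass,
    )

    thresholds = config.thresholds()
    calls: list[VariantRecord] = []
    per_amplicon: dict[str, dict] = {}
    for amp in panel:
        pile, amp_calls = call_amplicon(assigned, amp, thresholds)
        calls.extend(amp_calls)
        per_amplicon[amp.amplicon_id] = {
            "sequences": pile.n_sequences,
            "accepted_alignments": pile.n_accepted,
            "rejected_alignments": pile.n_rejected,
            "calls": len(amp_calls),
        }
    logger.info("calling: %d variants over %d amplicons", len(calls), len(panel))

    report = {
        "input_pairs": cleaning.input_pairs,
        "dropped_public": cleaning.dropped_public,
        "index_trimmed": cleaning.index_trimmed,
        "r1_truncated": cleaning.r1_truncated,
        "surviving_pairs": cleaning.surviving_pairs,
        "collapsed_distinct": len(collapsed),
        "collapsed_retained_pairs": n_retained,
        "selected_positions": list(catalog.selected_positions),
        "unassigned_sequences": n_unassigned,
        "unassigned_pairs": unassigned_mass,
        "n_calls": len(calls),
        "per_amplicon": per_amplicon,
    }
    if out_vcf is not None:
        write_variants(calls, out_vcf)
    if out_report is not None:
        _write_report(report, out_report)
    return calls, report


def _write_report(report: dict, path) -> None:
    rows = [
        (k, v) for k, v in report.items() if k != "per_amplicon"
    ]
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")
        for amp, stats in report["per_amplicon"].items():
            for k, v in stats.items():
                fh.write(f"{amp}.{k}\t{v}\n")


def run_simulate(
    panel,
    out_prefix,
    *,
    n_snps: int = 30,
    n_indels: int = 20,
    depth: int = 50,
    read_length: int = 150,
    error_rate: float = 0.0,
    allele_fraction: float = 0.5,
    seed: int = 0,
    n_amplicons: int = 20,
) -> tuple[str, str, str]:
    """Simulate a spike-in experiment; ``panel=None`` draws a synthetic one.

    Thin wrapper over :mod:`ampvar.simulation_eval`; writes the FASTQ
    pair and truth TSV under ``out_prefix`` and returns their paths.
    """
    if panel is None:
        panel = random_panel(n_amplicons, seed=seed)
    else:
        panel = _as_panel(panel)
    truth = random_truth(
        panel,
        n_snps=n_snps,
        n_indels=n_indels,
        depth=depth,
        allele_fraction=allele_fraction,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )
    return simulate_reads(panel, truth, out_prefix)


def run_evaluate(vcf_path, truth_path) -> pd.DataFrame:
    """Match a call VCF against a truth TSV and tabulate the metrics.

    Returns a DataFrame with one row per variant class (SNP, indel)
    holding the confusion counts, recall, TPR, FPR and accuracy.
    """
    calls = read_variants(vcf_path)
    _, target_lens, truth_ev = read_truth(truth_path)
    snp_cc, indel_cc = match_calls(calls, truth_ev, target_lens)
    rows = []
    for name, cc in (("SNP", snp_cc), ("Indel", indel_cc)):
        tpr, fpr, acc = tpr_fpr_accuracy(cc)
        rows.append(
            {
                "class": name,
                "TP": cc.tp,
                "FP": cc.fp,
                "FN": cc.fn,
                "TN": cc.tn,
                "recall": recall(cc),
                "TPR": tpr,
                "FPR": fpr,
                "accuracy": acc,
            }
        )
    return pd.DataFrame(rows)
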