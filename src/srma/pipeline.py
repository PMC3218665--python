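"""End-to-end simulated re-sequencing experiment.

Glue for the common experiment: simulate a diploid genome and reads,
produce stand-in initial alignments, re-align them, call variants on both
alignment sets with the same caller, and score each against the truth
table.  Used by the acceptance script and the integration tests; each step
is the public API of its module.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .evaluate import pileup_call, roc_curve, sensitivity_at_fpr
from .realign import RealignConfig
from .sam_io import iter_alignments, stream_realign, write_initial_alignments
from .simulate import (
    SimParams,
    generate_read_pairs,
    mutate_diploid,
    naive_initial_align,
    random_reference,
)


@dataclass
class ExperimentResult:
    reference: str
    truth: pd.DataFrame
    calls_before: pd.DataFrame
    calls_after: pd.DataFrame
    roc_before: pd.DataFrame
    roc_after: pd.DataFrame
    stats: object
    n_reads: int


def run_experiment(
    genome_length: int,
    seed: int,
    params: Optional[SimParams] = None,
    config: Optional[RealignConfig] = None,
    space: str = "base",
    workdir: Optional[str] = None,
    contig: str = "sim",
) -> ExperimentResult:
    """Simulate, align, re-align, call, and score one experiment.

    Runs through real SAM files on disk (in ``workdir`` or a temporary
    directory) so the streaming I/O path is exercised exactly as the CLI
    uses it.
    """
    params = params or SimParams()
    config = config or RealignConfig()
    reference = random_reference(genome_length, seed)
    hap_a, hap_b, truth = mutate_diploid(reference, params, seed + 1)
    reads = generate_read_pairs((hap_a, hap_b), params, seed + 2, space=space)
    aligns = naive_initial_align(reads, reference)

    own_tmp = None
    if workdir is None:
        own_tmp = tempfile.TemporaryDirectory(prefix="srma-")
        workdir = own_tmp.name
    try:
        before_path = os.path.join(workdir, "initial.bam")
        after_path = os.path.join(workdir, "realigned.bam")
        write_initial_alignments(before_path, aligns, contig, genome_length)
        stats = stream_realign(
            before_path, {contig: reference}, after_path, config
        )
        calls_before = pileup_call(
            iter_alignments(before_path), reference, base_error=params.base_error_rate
        )
        calls_after = pileup_call(
            iter_alignments(after_path), reference, base_error=params.base_error_rate
        )
    finally:
        if own_tmp is not None:
            own_tmp.cleanup()

    roc_before = roc_curve(calls_before, truth, genome_length)
    roc_after = roc_curve(calls_after, truth, genome_length)
    return ExperimentResult(
        reference=reference,
        truth=truth,
        calls_before=calls_before,
        calls_after=calls_after,
        roc_before=roc_before,
        roc_after=roc_after,
        stats=stats,
        n_reads=len(reads),
    )


def headline_sensitivity(result: ExperimentResult, max_fpr: float = 1e-6) -> dict:
    """Per-type sensitivity after re-alignment at the FPR bound."""
    return sensitivity_at_fpr(result.roc_after, max_fpr)
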