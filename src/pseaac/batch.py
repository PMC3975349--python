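"""Batch engine: run one mode over a FASTA stream and write a matrix.

The engine is strictly streaming — records are read, converted and
written one at a time, so peak memory is independent of the number of
sequences.  Record-level failures follow the run's skip policy: under
``on_error="abort"`` (the analogue of the strict ambiguity policy) any
failure stops the run naming the offending record; under ``"skip"`` the
record is logged, counted, and excluded from the output.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ConfigurationError, PseaacError
from .io import ProteinRecord, read_fasta
from .output import MatrixWriter
from .registry import Registry, Resources, default_resources, register_builtin_modes
from .vector import DescriptorVector

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one batch run needs."""

    mode: str
    fasta: object  # path or open handle
    out: object  # path or open handle
    params: dict = field(default_factory=dict)
    output_format: str = "csv"
    ambiguous_policy: str = "error"
    on_error: str = "abort"  # or "skip"
    resources: Resources | None = None

    def __post_init__(self):
        if self.on_error not in ("abort", "skip"):
            raise ConfigurationError(
                f"on_error must be 'abort' or 'skip', got {self.on_error!r}"
            )


@dataclass
class RunReport:
    """Counters and timings from one batch run."""

    mode: str
    records_read: int = 0
    records_written: int = 0
    records_skipped: int = 0
    skip_reasons: list[str] = field(default_factory=list)
    output_dim: int = 0
    elapsed_seconds: float = 0.0

    def summary(self) -> str:
        return (
            f"mode={self.mode} read={self.records_read} "
            f"written={self.records_written} skipped={self.records_skipped} "
            f"dim={self.output_dim} elapsed={self.elapsed_seconds:.2f}s"
        )


def _feature_names_probe(
    registry: Registry, config: RunConfig, resources: Resources
) -> tuple[str, ...]:
    """Feature names for the header, from a probe record long enough for
    any default lag/tier parameter.  Name layout depends only on mode +
    parameters, never on the sequence."""
    spec = registry.get(config.mode)
    params = spec.resolve_params(config.params)
    probe_len = 20 * (
        2 + max([v for v in params.values() if isinstance(v, int)] or [1])
    )
    probe_seq = ("ACDEFGHIKLMNPQRSTVWY" * (probe_len // 20 + 1))[:probe_len]
    probe = ProteinRecord(id="__probe__", seq=probe_seq)
    if config.mode == "psepssm":
        # synthesize a matching probe PSSM so the probe can run
        from .synthetic import synth_pssm

        resources.pssms.setdefault("__probe__", synth_pssm(0, probe))
        try:
            vec = registry.compute_checked(config.mode, probe, config.params, resources)
        finally:
            resources.pssms.pop("__probe__", None)
        return vec.feature_names
    vec = registry.compute_checked(config.mode, probe, config.params, resources)
    return vec.feature_names


def run_batch(
    config: RunConfig,
    registry: Registry | None = None,
    records: Iterable[ProteinRecord] | None = None,
) -> RunReport:
    """Execute one mode over all records; returns the run report.

    ``records`` overrides FASTA reading (used by callers that already
    hold an iterator); otherwise ``config.fasta`` is streamed with the
    configured ambiguity policy.
    """
    t0 = time.monotonic()
    if registry is None:
        registry = register_builtin_modes()
    resources = config.resources if config.resources is not None else default_resources()
    report = RunReport(mode=config.mode)

    feature_names = _feature_names_probe(registry, config, resources)
    report.output_dim = len(feature_names)

    if records is None:
        records = read_fasta(config.fasta, config.ambiguous_policy)

    out_handle, owns = _open_out(config.out)
    try:
        writer = MatrixWriter(out_handle, feature_names, config.output_format)
        for rec in records:
            report.records_read += 1
            try:
                vec = registry.compute_checked(
                    config.mode, rec, config.params, resources
                )
            except PseaacError as exc:
                if config.on_error == "abort":
                    raise
                report.records_skipped += 1
                report.skip_reasons.append(f"{rec.id}: {exc}")
                logger.warning("skipping %r: %s", rec.id, exc)
                continue
            writer.write_row(rec.id, vec.values)
            report.records_written += 1
    finally:
        if owns:
            out_handle.close()
    report.elapsed_seconds = time.monotonic() - t0
    logger.info("%s", report.summary())
    return report


def _open_out(target):
    if isinstance(target, (str, Path)):
        return open(target, "w", encoding="utf-8", newline="\n"), True
    return target, False
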