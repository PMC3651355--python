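"""Full-pipeline orchestration and incremental renormalization.

A run proceeds per chip through: reference selection (median chip by
all-vs-all RMSD when ``reference="auto"``), per-chip background
subtraction, probe-level pair-wise normalization against the reference,
Tukey-biweight probeset summarization, and a final probeset-level
pair-wise normalization against the reference's own summarized vector.
The reference chip passes through the normalization stages untouched (it
is background-subtracted and summarized like any other chip, never
curve-adjusted).

Because each chip depends only on itself, the reference, and the config, a
chip normalized alone (:func:`normalize_incremental`) is bit-identical to
the same chip normalized inside any batch — new chips can be added later
without altering previously normalized values.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .background_rma import correct_chip, estimate_bg_params
from .data_model import (
    ChipLayout,
    ExpressionMatrix,
    PipelineConfig,
    read_matrix,
    write_matrix,
)
from .pairwise_norm import NormalizationError, normalize_pair
from .reference_selection import find_median_chip
from .summarize import BiweightParams, summarize_probesets

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationReport",
    "ReferenceBundle",
    "build_reference_bundle",
    "run_iron",
    "normalize_incremental",
]


@dataclass
class NormalizationReport:
    """Per-sample diagnostics: pruning trajectory, convergence, correction
    range, stage timings.  The reference sample's record is marked
    ``identity``."""

    records: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.records.append(kw)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records)
        if "iteration_sizes" in df.columns:
            df["iteration_sizes"] = df["iteration_sizes"].map(
                lambda s: ";".join(str(v) for v in s) if isinstance(s, list) else s
            )
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ReferenceBundle:
    """Everything needed to normalize a chip without the rest of the batch:
    the reference's raw and background-corrected probe vectors, its
    summarized probeset vector (when a layout is in play), and a fingerprint
    binding the bundle to the config that produced it."""

    feature_ids: list[str]
    raw: np.ndarray
    corrected: np.ndarray
    fingerprint: str
    sample_id: str
    probeset_ids: list[str] | None = None
    summarized: np.ndarray | None = None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        probe = ExpressionMatrix(
            self.feature_ids, ["raw", "corrected"],
            np.column_stack([self.raw, self.corrected]), "linear",
        )
        write_matrix(probe, directory / "reference_probes.tsv", precision=17)
        meta = {"fingerprint": self.fingerprint, "sample_id": self.sample_id}
        if self.summarized is not None:
            ps = ExpressionMatrix(
                self.probeset_ids, ["summarized"],
                self.summarized[:, None], "linear",
            )
            write_matrix(ps, directory / "reference_probesets.tsv", precision=17)
            meta["has_probesets"] = True
        (directory / "reference_meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceBundle":
        directory = Path(directory)
        meta = json.loads((directory / "reference_meta.json").read_text())
        probe = read_matrix(directory / "reference_probes.tsv")
        probeset_ids = summarized = None
        if meta.get("has_probesets"):
            ps = read_matrix(directory / "reference_probesets.tsv")
            probeset_ids = ps.feature_ids
            summarized = ps.values[:, 0]
        return cls(
            feature_ids=probe.feature_ids,
            raw=probe.values[:, 0],
            corrected=probe.values[:, 1],
            fingerprint=meta["fingerprint"],
            sample_id=meta["sample_id"],
            probeset_ids=probeset_ids,
            summarized=summarized,
        )


def _fingerprint(config: PipelineConfig, raw_reference: np.ndarray) -> str:
    import hashlib

    h = hashlib.sha256(config.fingerprint().encode())
    h.update(np.ascontiguousarray(raw_reference, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _bg_correct(chip: np.ndarray, config: PipelineConfig) -> np.ndarray:
    if not config.do_background:
        return np.asarray(chip, dtype=float)
    return correct_chip(chip, estimate_bg_params(chip))


def _summarize_vector(
    vector: np.ndarray,
    feature_ids: list[str],
    layout: ChipLayout,
    biweight: BiweightParams,
) -> tuple[list[str], np.ndarray]:
    one = ExpressionMatrix(list(feature_ids), ["_"], np.asarray(vector, float)[:, None])
    summary = summarize_probesets(one, layout, biweight)
    return summary.feature_ids, summary.values[:, 0]


def build_reference_bundle(
    raw_reference: np.ndarray,
    feature_ids: list[str],
    config: PipelineConfig,
    layout: ChipLayout | None = None,
    biweight: BiweightParams | None = None,
    sample_id: str = "reference",
) -> ReferenceBundle:
    """Prepare a reference chip for (batch or incremental) normalization."""
    raw = np.asarray(raw_reference, dtype=float)
    corrected = _bg_correct(raw, config)
    probeset_ids = summarized = None
    if layout is not None:
        probeset_ids, summarized = _summarize_vector(
            corrected, feature_ids, layout, biweight or BiweightParams()
        )
    return ReferenceBundle(
        feature_ids=list(feature_ids),
        raw=raw,
        corrected=corrected,
        fingerprint=_fingerprint(config, raw),
        sample_id=sample_id,
        probeset_ids=probeset_ids,
        summarized=summarized,
    )


def _process_chip(
    raw_chip: np.ndarray,
    bundle: ReferenceBundle,
    layout: ChipLayout | None,
    config: PipelineConfig,
    biweight: BiweightParams,
    sample_id: str,
) -> tuple[np.ndarray, dict]:
    """One chip through background → probe norm → summarize → probeset norm.

    This single code path serves both batch runs and incremental mode, which
    is what makes the two bit-identical.
    """
    t0 = time.perf_counter()
    raw_chip = np.asarray(raw_chip, dtype=float)
    corrected = _bg_correct(raw_chip, config)
    try:
        probe_norm, _curve, _training, rec = normalize_pair(
            corrected,
            bundle.corrected,
            layout=layout,
            config=config,
            feature_ids=bundle.feature_ids,
            training_sample=raw_chip,
            training_reference=bundle.raw,
        )
    except NormalizationError as exc:
        raise NormalizationError(f"sample {sample_id!r}, probe-level stage: {exc}") from exc
    record = {"sample_id": sample_id, "identity": False, **rec}
    output = probe_norm
    if layout is not None:
        _ids, summarized = _summarize_vector(
            probe_norm, bundle.feature_ids, layout, biweight
        )
        output = summarized
        if config.do_probeset_norm:
            try:
                output, _c, _t, ps_rec = normalize_pair(
                    summarized, bundle.summarized, layout=None, config=config
                )
            except NormalizationError as exc:
                raise NormalizationError(
                    f"sample {sample_id!r}, probeset-level stage: {exc}"
                ) from exc
            record.update({f"probeset_{k}": v for k, v in ps_rec.items()})
    record["seconds"] = round(time.perf_counter() - t0, 4)
    return output, record


def run_iron(
    matrix: ExpressionMatrix,
    layout: ChipLayout | None = None,
    config: PipelineConfig | None = None,
    reference: str = "auto",
    biweight: BiweightParams | None = None,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Run the whole pipeline on a matrix.

    ``reference`` names a sample or is ``"auto"`` (median chip by RMSD on
    the raw matrix).  Returns the probeset-level matrix when a layout is
    given (probe-level otherwise) and a per-sample report.
    """
    config = config or PipelineConfig()
    biweight = biweight or BiweightParams()
    matrix.require_scale("linear")
    if matrix.n_samples < 2:
        raise ValueError("need ≥ 2 samples")
    if reference == "auto":
        ref_id, _table = find_median_chip(matrix, layout, log_base=config.log_base)
        logger.info("auto-selected reference chip: %s", ref_id)
    else:
        ref_id = reference
        if ref_id not in matrix.sample_ids:
            raise ValueError(f"reference sample {ref_id!r} not in matrix")

    bundle = build_reference_bundle(
        matrix.column(ref_id), matrix.feature_ids, config, layout, biweight, ref_id
    )

    report = NormalizationReport()
    columns: dict[str, np.ndarray] = {}
    for sid in matrix.sample_ids:
        if sid == ref_id:
            out = bundle.summarized if layout is not None else bundle.corrected
            columns[sid] = np.asarray(out, dtype=float)
            report.add(sample_id=sid, identity=True, iterations=0,
                       converged=True, iteration_sizes=[])
        else:
            out, rec = _process_chip(
                matrix.column(sid), bundle, layout, config, biweight, sid
            )
            columns[sid] = out
            report.add(**rec)
            logger.info(
                "normalized %s: %d→%d training probes in %d iterations",
                sid, rec["initial_training_size"], rec["final_training_size"],
                rec["iterations"],
            )
    out_ids = bundle.probeset_ids if layout is not None else bundle.feature_ids
    out = ExpressionMatrix(
        list(out_ids),
        list(matrix.sample_ids),
        np.column_stack([columns[s] for s in matrix.sample_ids]),
        "linear",
    )
    return out, report


def normalize_incremental(
    new_chip: np.ndarray,
    feature_ids: list[str],
    bundle: ReferenceBundle,
    layout: ChipLayout | None = None,
    config: PipelineConfig | None = None,
    biweight: BiweightParams | None = None,
    sample_id: str = "new_chip",
) -> tuple[np.ndarray, dict]:
    """Normalize one new chip against a stored reference.

    The chip must share the reference's exact feature order and the config
    must match the one fingerprinted into the bundle; both are validated,
    never silently fixed.  The output is bit-identical to what the chip
    would receive inside a full batch run with the same reference.
    """
    config = config or PipelineConfig()
    feature_ids = [str(f) for f in feature_ids]
    if feature_ids != bundle.feature_ids:
        for i, (got, want) in enumerate(zip(feature_ids, bundle.feature_ids)):
            if got != want:
                raise ValueError(
                    f"feature order mismatch at position {i}: {got!r} != {want!r}"
                )
        raise ValueError(
            f"feature count mismatch: {len(feature_ids)} vs {len(bundle.feature_ids)}"
        )
    if _fingerprint(config, bundle.raw) != bundle.fingerprint:
        raise ValueError("config fingerprint does not match the stored reference")
    return _process_chip(
        np.asarray(new_chip, dtype=float), bundle, layout, config,
        biweight or BiweightParams(), sample_id,
    )
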