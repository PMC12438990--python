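"""End-to-end pipeline: simulate/ingest -> sequences -> entropy -> shifts ->
hazard contrasts -> plots, with a reproducibility manifest.

The pipeline is configured by a plain dict (usually loaded from YAML); any
stage failure aborts with a stage-named :class:`StageError` while partial
outputs are retained.  The manifest records package and library versions,
the seed, a hash of the resolved configuration and per-stage row counts,
and contains no timestamps, so a rerun with the same configuration and seed
produces byte-identical tabular outputs and an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

from . import __version__
from .entropy import compare_entropy_groups, entropy_by_person, summarize_entropy
from .records import identify_d1, read_records, write_records
from .sequences import (
    build_sequence_set,
    build_sequences,
    sequences_to_frame,
)
from .shifts import (
    record_level_shift_summary,
    shift_summary,
    shift_summary_by_sex,
    top_subsequent_categories,
)
from .simulate import SyntheticCohortConfig, generate_cohort
from .survival import hazard_grid
from .taxonomy import CategoryTaxonomy


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_demo_config() -> dict[str, Any]:
    """Small self-contained demo configuration (simulated cohort)."""
    return {
        "simulate": {"n_persons": 300},
        "seed": 7,
        "stratifiers": ["d1", "sex"],
        "alphabet_size": 21,
        "min_count": 5,
        "entropy_contrast": "age_band",
        "cox": True,
        "plots": True,
    }


def _config_hash(config: dict[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _write_csv(df, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: dict[str, Any], out_dir: str | Path,
                 seed: int | None = None) -> dict[str, Any]:
    """Execute the configured pipeline into ``out_dir``; returns the manifest.

    Config keys: ``simulate`` (dict of cohort-config overrides) or
    ``records`` (path to an event file); optional ``taxonomy`` (path),
    ``stratifiers``, ``alphabet_size``, ``min_count``, ``entropy_contrast``
    (a stratifier to contrast mean entropy over), ``cox`` and ``plots``
    (bools), ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = {**config, "seed": seed}
    manifest: dict[str, Any] = {
        "package": "diagtraj",
        "version": __version__,
        "seed": config.get("seed"),
        "config_sha256": _config_hash(config),
        "stages": {},
    }
    import lifelines, matplotlib, numpy, pandas, scipy  # noqa: E401

    manifest["library_versions"] = {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
        "matplotlib": matplotlib.__version__,
    }

    # ---------------------------------------------------------------- setup
    try:
        tax_path = config.get("taxonomy")
        taxonomy = (
            CategoryTaxonomy.from_file(tax_path) if tax_path
            else CategoryTaxonomy.default()
        )
    except Exception as exc:
        raise StageError("taxonomy", exc)

    # ------------------------------------------------------- simulate/ingest
    try:
        if "simulate" in config:
            overrides = dict(config["simulate"])
            overrides.setdefault("seed", config.get("seed", 0))
            cohort_config = SyntheticCohortConfig.default(**overrides)
            records, truth = generate_cohort(cohort_config, taxonomy)
            write_records(records, out_dir / "records.csv")
            (out_dir / "truth.json").write_text(
                json.dumps(truth.to_json_dict(), sort_keys=True) + "\n"
            )
            manifest["stages"]["simulate"] = {"n_records": len(records)}
        elif "records" in config:
            records = None  # path checked by the ingest stage
        else:
            raise ValueError("config needs 'simulate' or 'records'")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", exc)

    try:
        records_path = (
            out_dir / "records.csv" if "simulate" in config else Path(config["records"])
        )
        records, report = read_records(records_path)
        report.to_json(out_dir / "ingest_report.json")
        cohort = identify_d1(records)
        manifest["stages"]["ingest"] = {
            "n_rows": report.n_rows,
            "n_accepted": report.n_accepted,
            "n_rejected": report.n_rejected,
            "n_persons": len(cohort.d1),
            "n_excluded_persons": len(cohort.excluded),
        }
    except Exception as exc:
        raise StageError("ingest", exc)

    # ------------------------------------------------------------ sequences
    try:
        sequences = build_sequences(cohort, taxonomy)
        _write_csv(sequences_to_frame(sequences, wide=True),
                   out_dir / "sequences_wide.csv")
        _write_csv(sequences_to_frame(sequences, wide=False),
                   out_dir / "sequences_long.csv")
        stratifiers = tuple(config.get("stratifiers", ("d1", "sex")))
        sets = build_sequence_set(sequences, stratifiers)
        manifest["stages"]["sequences"] = {
            "n_sequences": len(sequences),
            "n_strata": len(sets),
        }
    except Exception as exc:
        raise StageError("sequences", exc)

    # -------------------------------------------------------------- entropy
    try:
        a = int(config.get("alphabet_size", 21))
        min_count = int(config.get("min_count", 5))
        _write_csv(entropy_by_person(sequences, a), out_dir / "entropy_person.csv")
        summary = summarize_entropy(sets, a, min_count)
        _write_csv(summary, out_dir / "entropy_summary.csv")
        contrast_key = config.get("entropy_contrast")
        if contrast_key:
            from .sequences import StateSequence  # noqa: F401

            getter = {
                "sex": lambda q: q.sex,
                "age_band": lambda q: q.age_band_at_d1,
                "education": lambda q: q.parental_education,
            }[contrast_key]
            groups: dict[str, list[float]] = {}
            from .entropy import normalized_entropy

            for q in sequences:
                groups.setdefault(getter(q), []).append(normalized_entropy(q, a))
            result = compare_entropy_groups(groups)
            (out_dir / "entropy_tests.json").write_text(
                json.dumps({contrast_key: result.to_dict()}, sort_keys=True) + "\n"
            )
        manifest["stages"]["entropy"] = {"n_strata": len(summary)}
    except Exception as exc:
        raise StageError("entropy", exc)

    # --------------------------------------------------------------- shifts
    try:
        _write_csv(shift_summary(sets), out_dir / "shift_summary.csv")
        _write_csv(shift_summary_by_sex(sequences), out_dir / "shift_by_sex.csv")
        _write_csv(record_level_shift_summary(cohort, taxonomy),
                   out_dir / "shift_by_sex_record_level.csv")
        top_dir = out_dir / "top_sd"
        top_dir.mkdir(exist_ok=True)
        for sset in sets:
            if len(sset) < min_count:
                continue
            table = top_subsequent_categories(sset, k=5, min_count=min_count)
            _write_csv(table, top_dir / ("_".join(sset.label) + ".csv"))
        manifest["stages"]["shifts"] = {"n_strata": len(sets)}
    except Exception as exc:
        raise StageError("shifts", exc)

    # ------------------------------------------------------------------ cox
    if config.get("cox", True):
        try:
            grid = hazard_grid(cohort, taxonomy)
            _write_csv(grid, out_dir / "cox_contrasts.csv")
            manifest["stages"]["cox"] = {
                "n_contrasts": len(grid),
                "n_tests": int(grid["n_tests"].iloc[0]) if len(grid) else 0,
            }
        except Exception as exc:
            raise StageError("cox", exc)

    # ---------------------------------------------------------------- plots
    if config.get("plots", True):
        try:
            from .plotting import plot_entropy_bars, plot_sequence_frequency

            plot_dir = out_dir / "plots"
            plot_dir.mkdir(exist_ok=True)
            plotted = 0
            for sset in sets:
                if len(sset) < min_count:
                    continue
                plot_sequence_frequency(
                    sset, plot_dir / ("freq_" + "_".join(sset.label) + ".png"),
                    min_count=min_count,
                )
                plotted += 1
            plot_entropy_bars(summary, plot_dir / "entropy_bars.png")
            manifest["stages"]["plots"] = {"n_plots": plotted + 1}
        except Exception as exc:
            raise StageError("plots", exc)

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
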