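"""Run configuration, CSV input/output and the end-to-end pipeline runner.

All tabular I/O is plain CSV with fixed column contracts (these survey
summaries have no domain-standard container format); the run configuration
is a human-readable ``key: value`` text file.  Every output table carries
the configuration hash on a leading comment line, and a manifest records
the configuration, package and library versions, the seed and the warning
counters (dropped grid pairs, floored consumption days, clamped
energy-density evaluations) so a run is reproducible and auditable.

Input file contracts (all CSV, within ``input_dir``):

- ``temperature.csv``:    species, year, period, cell_id, depth_mid_m, value
- ``density.csv``:        species, year, period, cell_id, depth_mid_m, value, kind
- ``seasonal_samples.csv``: species, year, doy, length_cm, weight_g
- ``winter_samples.csv``: species, year, age, length_cm
- ``numbers_at_age.csv``: species, year, age, numbers, mean_weight_g
- ``biomass.csv``:        species, year, biomass_tonnes, kind
- ``diet.csv``:           species, year, season, seven prey-group columns, source
- ``k.csv`` (optional):   species, year, k
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .diet import load_diet_table
from .model import ConsumptionModel, ConsumptionResults, ModelOptions, SpeciesInputs
from .species import DEFAULT_SPECIES, Species
from .temperature import GriddedField

log = logging.getLogger(__name__)

INPUT_FILES = {
    "temperature": "temperature.csv",
    "density": "density.csv",
    "seasonal": "seasonal_samples.csv",
    "winter": "winter_samples.csv",
    "naa": "numbers_at_age.csv",
    "biomass": "biomass.csv",
    "diet": "diet.csv",
    "k": "k.csv",  # optional
}


class InputError(ValueError):
    """Missing or malformed input data or configuration (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_dir: Path
    output_dir: Path
    species: list[str] = field(
        default_factory=lambda: [s.value for s in Species]
    )
    years: list[int] | None = None  # None: all years in the biomass table
    seed: int = 0
    biomass_ref: str = "t91"
    rate_weighting: str = "gram_days"

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        valid = {s.value for s in Species}
        unknown = set(self.species) - valid
        if unknown:
            raise InputError(f"unknown species {sorted(unknown)}; valid: {sorted(valid)}")
        if self.biomass_ref not in ("t91", "feeding_start"):
            raise InputError(f"biomass_ref must be t91|feeding_start, got {self.biomass_ref}")
        if self.rate_weighting not in ("gram_days", "per_fish"):
            raise InputError(
                f"rate_weighting must be gram_days|per_fish, got {self.rate_weighting}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        kv: dict[str, str] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise InputError(f"{path}:{lineno}: expected 'key: value'")
            k, _, v = line.partition(":")
            kv[k.strip()] = v.strip()
        try:
            kwargs: dict = {
                "input_dir": kv.pop("input_dir"),
                "output_dir": kv.pop("output_dir"),
            }
        except KeyError as err:
            raise InputError(f"config missing required key {err}") from None
        if "species" in kv:
            kwargs["species"] = [s.strip() for s in kv.pop("species").split(",")]
        if "years" in kv:
            kwargs["years"] = [int(y) for y in kv.pop("years").split(",")]
        for key in ("biomass_ref", "rate_weighting"):
            if key in kv:
                kwargs[key] = kv.pop(key)
        if "seed" in kv:
            kwargs["seed"] = int(kv.pop("seed"))
        if kv:
            raise InputError(f"unknown config keys: {sorted(kv)}")
        return cls(**kwargs)

    def to_text(self) -> str:
        lines = [
            f"input_dir: {self.input_dir}",
            f"output_dir: {self.output_dir}",
            f"species: {', '.join(self.species)}",
        ]
        if self.years is not None:
            lines.append(f"years: {', '.join(map(str, self.years))}")
        lines += [
            f"seed: {self.seed}",
            f"biomass_ref: {self.biomass_ref}",
            f"rate_weighting: {self.rate_weighting}",
        ]
        return "\n".join(lines) + "\n"

    @property
    def hash(self) -> str:
        """Hash of the computation-relevant configuration.

        The output directory does not affect the results and is excluded, so
        the same run written to two places carries the same hash.
        """
        relevant = "\n".join(
            line
            for line in self.to_text().splitlines()
            if not line.startswith("output_dir:")
        )
        return hashlib.sha256(relevant.encode()).hexdigest()[:12]


def _read_csv(path: Path, required: set[str]) -> pd.DataFrame:
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:  # malformed CSV
        raise InputError(f"cannot parse {path}: {err}") from err
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_inputs(config: RunConfig) -> dict[Species, SpeciesInputs]:
    """Load and validate all input CSVs into per-species bundles."""
    d = config.input_dir
    temps = _read_csv(
        d / INPUT_FILES["temperature"],
        {"species", "year", "period", "cell_id", "depth_mid_m", "value"},
    )
    dens = _read_csv(
        d / INPUT_FILES["density"],
        {"species", "year", "period", "cell_id", "depth_mid_m", "value", "kind"},
    )
    seasonal = _read_csv(
        d / INPUT_FILES["seasonal"], {"species", "year", "doy", "length_cm", "weight_g"}
    )
    winter = _read_csv(
        d / INPUT_FILES["winter"], {"species", "year", "age", "length_cm"}
    )
    naa = _read_csv(
        d / INPUT_FILES["naa"],
        {"species", "year", "age", "numbers", "mean_weight_g"},
    )
    biomass = _read_csv(
        d / INPUT_FILES["biomass"], {"species", "year", "biomass_tonnes", "kind"}
    )
    diet_path = d / INPUT_FILES["diet"]
    if not diet_path.exists():
        raise InputError(f"input file not found: {diet_path}")
    diet = load_diet_table(diet_path)
    k_path = d / INPUT_FILES["k"]
    ktbl = pd.read_csv(k_path) if k_path.exists() else None

    inputs: dict[Species, SpeciesInputs] = {}
    for name in config.species:
        sp = Species(name)
        sp_fields = {}
        t_sp = temps[temps["species"] == name]
        d_sp = dens[dens["species"] == name]
        for (year, period), tgrp in t_sp.groupby(["year", "period"]):
            dgrp = d_sp[(d_sp["year"] == year) & (d_sp["period"] == period)]
            if dgrp.empty:
                raise InputError(f"{name} {year} {period}: no density field")
            kind = str(dgrp["kind"].iloc[0])
            sp_fields[(int(year), str(period))] = (
                GriddedField(str(period), "temperature", tgrp.reset_index(drop=True)),
                GriddedField(str(period), kind, dgrp.reset_index(drop=True)),
            )
        if not sp_fields:
            raise InputError(f"no gridded fields for species {name}")
        k_by_year = None
        if ktbl is not None:
            rows = ktbl[ktbl["species"] == name]
            if not rows.empty:
                k_by_year = {int(r["year"]): float(r["k"]) for _, r in rows.iterrows()}
        inputs[sp] = SpeciesInputs(
            params=DEFAULT_SPECIES[sp],
            fields=sp_fields,
            seasonal_samples=seasonal[seasonal["species"] == name],
            winter_samples=winter[winter["species"] == name],
            numbers_at_age=naa[naa["species"] == name],
            biomass=biomass[biomass["species"] == name],
            diet=[c for c in diet if c.species == name],
            k_by_year=k_by_year,
        )
    return inputs


class _WarningCounter(logging.Handler):
    """Counts pipeline warning events by category for the run manifest."""

    CATEGORIES = {
        "dropped_grid_pairs": "dropped",
        "floored_consumption_days": "floored",
        "clamped_ed_evaluations": "clamping",
    }

    def __init__(self) -> None:
        super().__init__(level=logging.INFO)
        self.counts = {name: 0 for name in self.CATEGORIES}

    def emit(self, record: logging.LogRecord) -> None:
        msg = record.getMessage()
        for name, needle in self.CATEGORIES.items():
            if needle in msg:
                self.counts[name] += 1


def write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    """Write a CSV output table with the configuration hash on a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, expect_hash: str | None = None) -> pd.DataFrame:
    """Read an output table, optionally checking its configuration hash."""
    path = Path(path)
    first = path.read_text().split("\n", 1)[0]
    if expect_hash is not None:
        got = first.removeprefix("# config_hash=").strip()
        if got != expect_hash:
            raise InputError(
                f"{path}: config hash {got!r} does not match expected {expect_hash!r}"
            )
    return pd.read_csv(path, comment="#")


def run_pipeline(config: RunConfig) -> ConsumptionResults:
    """Execute the full pipeline from CSV inputs and write output tables.

    Outputs in ``config.output_dir``: daily/monthly/annual consumption
    tables, specific rates, C/B ratios, the serialized configuration and a
    manifest with versions, seed and warning counters.
    """
    inputs = load_inputs(config)
    counter = _WarningCounter()
    pkg_logger = logging.getLogger("planktivore")
    pkg_logger.addHandler(counter)
    try:
        model = ConsumptionModel(
            inputs,
            years=config.years,
            options=ModelOptions(
                biomass_ref=config.biomass_ref,
                rate_weighting=config.rate_weighting,
            ),
        )
        results = model.fit()
    finally:
        pkg_logger.removeHandler(counter)

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash
    write_table(results.table.daily, out / "consumption_daily.csv", h)
    write_table(results.table.monthly(), out / "consumption_monthly.csv", h)
    write_table(results.table.annual_by_group(), out / "consumption_annual.csv", h)
    write_table(results.specific_rates(), out / "specific_rates.csv", h)
    write_table(results.cb_ratios(), out / "cb_ratios.csv", h)
    write_table(results.diagnostics, out / "diagnostics.csv", h)
    (out / "config.cfg").write_text(config.to_text())

    import numpy
    import scipy

    from . import __version__

    manifest = [
        f"config_hash: {h}",
        f"planktivore: {__version__}",
        f"numpy: {numpy.__version__}",
        f"pandas: {pd.__version__}",
        f"scipy: {scipy.__version__}",
        f"seed: {config.seed}",
    ]
    manifest += [f"warnings.{k}: {v}" for k, v in sorted(counter.counts.items())]
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return results


def write_synthetic_inputs(scenario, out_dir: str | Path) -> Path:
    """Emit a full synthetic input bundle as CSVs into a directory."""
    from .synthetic import (
        generate_assessment,
        generate_fish_samples,
        generate_temperature_fields,
        load_k_table,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    temp_rows, dens_rows, seasonal_all, winter_all, naa_all, bio_all = (
        [],
        [],
        [],
        [],
        [],
        [],
    )
    for sp in scenario.species:
        for year in scenario.years:
            for period, (temps, dens) in generate_temperature_fields(
                scenario, sp, year
            ).items():
                t = temps.data.assign(species=sp.value, year=year)
                d = dens.data.assign(species=sp.value, year=year, kind=dens.kind)
                temp_rows.append(t)
                dens_rows.append(d)
        seasonal, winter = generate_fish_samples(scenario, sp)
        naa, biomass = generate_assessment(scenario, sp)
        seasonal_all.append(seasonal)
        winter_all.append(winter)
        naa_all.append(naa)
        bio_all.append(biomass)

    pd.concat(temp_rows, ignore_index=True).to_csv(
        out / INPUT_FILES["temperature"], index=False
    )
    pd.concat(dens_rows, ignore_index=True).to_csv(
        out / INPUT_FILES["density"], index=False
    )
    pd.concat(seasonal_all, ignore_index=True).to_csv(
        out / INPUT_FILES["seasonal"], index=False
    )
    pd.concat(winter_all, ignore_index=True).to_csv(
        out / INPUT_FILES["winter"], index=False
    )
    pd.concat(naa_all, ignore_index=True).to_csv(out / INPUT_FILES["naa"], index=False)
    pd.concat(bio_all, ignore_index=True).to_csv(
        out / INPUT_FILES["biomass"], index=False
    )
    from importlib import resources

    with resources.as_file(
        resources.files("planktivore.data").joinpath("diet_table.csv")
    ) as p:
        (out / INPUT_FILES["diet"]).write_text(Path(p).read_text())
    load_k_table().to_csv(out / INPUT_FILES["k"], index=False)
    return out
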