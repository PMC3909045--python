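"""Synthetic glycolipid-agonist data with known ground truth.

Real structure–immune datasets for iNKT-cell agonists are aggregated from
dozens of publications and are not redistributable, so every downstream
stage of this package is exercised on simulated data instead.  The
generator emulates the salient features of such a dataset:

* a compound × descriptor matrix with a correlated "informative" block,
  independent nuisance descriptors and a number of constant columns (real
  descriptor sets contain many);
* multi-study cytokine measurements per (compound, test-system, marker)
  cell, with lognormal inter-study noise applied on the ratio scale and a
  sparse measurement pattern;
* a linear descriptor → log-response ground truth in which IFN-γ and IL-4
  carry opposite-signed coefficients, so that compounds at the extremes of
  the informative axis are Th1 or Th2 polarizers — a non-trivial
  classification task for the downstream models;
* three doses per study with a peaked reference dose–response, so the
  "condition where the reference is maximal" selection rule has work to do.

The reference compound (α-GalCer stand-in) has all-zero informative
descriptors, hence an expected normalized response of exactly 1 in every
cell, and is measured in every generated study.  All output is a pure
function of the seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import MARKERS, TEST_SYSTEMS

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_chemical_space",
    "generate_response_studies",
    "generate_dataset",
    "generate_fixture_suite",
    "coefficient_scale_for_r2",
    "recovery_benchmark_config",
]

#: doses emitted per study and the reference compound's response profile
#: over them (peaked at the middle dose so dose selection is non-trivial)
DOSES: tuple[float, float, float] = (0.1, 1.0, 10.0)
REFERENCE_DOSE_PROFILE: tuple[float, float, float] = (0.5, 1.0, 0.7)
REFERENCE_BASELINE: float = 100.0


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study conditions for the simulated dataset.

    Parameters
    ----------
    n_compounds, n_descriptors : int
        Size of the descriptor matrix (compound 1 is the reference).
    n_informative : int
        Leading descriptors that carry signal; they form a correlated block.
    n_constant : int
        Trailing zero-variance descriptor columns.
    block_correlation : float
        Target pairwise correlation inside the informative block, in [0, 1).
    coefficient_scale : float
        Magnitude of each informative coefficient on the log-response scale.
    study_noise_cv : float
        Coefficient of variation of the lognormal inter-study noise applied
        to the analogue/reference response ratio.
    n_studies_min, n_studies_max : int
        Replicate studies per measured (compound, cell), uniform integer.
    measure_prob : float or mapping
        Probability that a (compound, test-system, marker) cell is measured
        at all; a mapping ``(test_system, marker) -> p`` gives a sparse
        pattern resembling the uneven usage of assays in the literature.
    seed : int
        Fully determines all output.
    """

    n_compounds: int = 60
    n_descriptors: int = 40
    n_informative: int = 5
    n_constant: int = 3
    block_correlation: float = 0.7
    coefficient_scale: float = 0.35
    study_noise_cv: float = 0.5
    n_studies_min: int = 1
    n_studies_max: int = 3
    measure_prob: float | dict = 0.7
    seed: int = 0
    systems: tuple = TEST_SYSTEMS
    markers: tuple = MARKERS
    reference_id: str = field(default="CPD-001", repr=False)

    def validate(self) -> None:
        if self.n_compounds < 2:
            raise ConfigurationError("need at least 2 compounds (reference + 1)")
        if not (0 <= self.n_informative <= self.n_descriptors - self.n_constant):
            raise ConfigurationError(
                "n_informative must fit within the non-constant descriptors")
        if self.n_constant < 0 or self.n_constant > self.n_descriptors:
            raise ConfigurationError("n_constant out of range")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ConfigurationError("block_correlation must be in [0, 1)")
        if self.study_noise_cv < 0:
            raise ConfigurationError("study_noise_cv must be >= 0")
        if not (1 <= self.n_studies_min <= self.n_studies_max):
            raise ConfigurationError("need 1 <= n_studies_min <= n_studies_max")
        probs = (self.measure_prob.values()
                 if isinstance(self.measure_prob, dict) else [self.measure_prob])
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("measure_prob must be in [0, 1]")
        if any(s not in TEST_SYSTEMS for s in self.systems):
            raise ConfigurationError("unknown test-system in config.systems")
        if any(m not in MARKERS for m in self.markers):
            raise ConfigurationError("unknown marker in config.markers")

    def cell_prob(self, system: str, marker: str) -> float:
        if isinstance(self.measure_prob, dict):
            return float(self.measure_prob.get((system, marker), 0.0))
        return float(self.measure_prob)


@dataclass
class GroundTruth:
    """True data-generating parameters behind a simulated dataset."""

    coefficients: dict  # (test_system, marker) -> ndarray over descriptors
    reference_compound_id: str
    informative_indices: list
    descriptor_names: list

    def coefficient_frame(self) -> pd.DataFrame:
        """Coefficients as a (test_system, marker) × descriptor table."""
        idx = pd.MultiIndex.from_tuples(self.coefficients, names=["test_system", "marker"])
        return pd.DataFrame(
            np.vstack([self.coefficients[k] for k in self.coefficients]),
            index=idx, columns=self.descriptor_names)

    def to_json(self) -> str:
        payload = {
            "reference_compound_id": self.reference_compound_id,
            "informative_indices": [int(i) for i in self.informative_indices],
            "descriptor_names": list(self.descriptor_names),
            "coefficients": {f"{s}|{m}": [float(v) for v in vec]
                             for (s, m), vec in self.coefficients.items()},
        }
        return json.dumps(payload, ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        coeffs = {}
        for key, vec in payload["coefficients"].items():
            system, marker = key.rsplit("|", 1)
            coeffs[(system, marker)] = np.asarray(vec, dtype=float)
        return cls(coefficients=coeffs,
                   reference_compound_id=payload["reference_compound_id"],
                   informative_indices=list(payload["informative_indices"]),
                   descriptor_names=list(payload["descriptor_names"]))


# Marker polarity on the log-response scale, relative to the shared
# informative direction: IFN-γ up ⇒ Th1 end, IL-4/IL-13 down, and vice versa.
_MARKER_SIGN = {"IFN-γ": 1.0, "IL-2": 0.5, "IL-4": -1.0, "IL-13": -0.5}


def coefficient_scale_for_r2(r2: float, study_noise_cv: float = 0.5,
                             n_informative: int = 5, block_correlation: float = 0.7,
                             n_studies: int = 1) -> float:
    """Coefficient magnitude giving roughly the requested R² on the
    log-response scale.

    Signal variance of x·β with k equal positive coefficients c on an
    equicorrelated(ρ) unit-variance block is c²·k·(1 + ρ(k−1)); averaging m
    lognormal study replicates of CV leaves residual log-scale variance
    ≈ ln(1 + cv²/m).
    """
    if not 0 < r2 < 1:
        raise ConfigurationError("r2 must be in (0, 1)")
    sigma2 = math.log(1.0 + study_noise_cv ** 2 / n_studies)
    per_c2 = n_informative * (1.0 + block_correlation * (n_informative - 1))
    return math.sqrt(r2 / (1.0 - r2) * sigma2 / per_c2)


def recovery_benchmark_config(seed: int) -> GeneratorConfig:
    """Conditions of the parameter-recovery benchmark.

    150 compounds × 50 descriptors, 5 informative at modest block
    correlation (0.3, so each informative descriptor keeps a clearly
    identifiable unique contribution), single study per cell, 50% study
    noise, coefficient magnitude calibrated analytically for R² ≈ 0.8 on
    the log-response scale.  Only the mice/in-vivo IFN-γ cell is generated
    — one regression task per seed.
    """
    c = coefficient_scale_for_r2(0.8, study_noise_cv=0.5, n_informative=5,
                                 block_correlation=0.3, n_studies=1)
    return GeneratorConfig(
        n_compounds=150, n_descriptors=50, n_informative=5, n_constant=0,
        block_correlation=0.3, coefficient_scale=c, study_noise_cv=0.5,
        n_studies_min=1, n_studies_max=1, measure_prob=1.0, seed=seed,
        systems=("mice/in-vivo",), markers=("IFN-γ",))


def _compound_ids(n: int) -> list[str]:
    return [f"CPD-{i + 1:03d}" for i in range(n)]


def generate_chemical_space(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a compound × descriptor matrix and its response coefficients.

    Layout: descriptors ``0 .. n_informative-1`` form the correlated signal
    block, the trailing ``n_constant`` columns are constant, the rest are
    independent noise.  The reference compound's informative entries are
    zeroed so its expected normalized response is exactly 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_compounds, config.n_descriptors, config.n_informative
    b = config.block_correlation

    X = rng.standard_normal((n, p))
    if k > 0 and b > 0:
        latent = rng.standard_normal(n)
        X[:, :k] = (math.sqrt(b) * latent[:, None]
                    + math.sqrt(1.0 - b) * rng.standard_normal((n, k)))
    if config.n_constant > 0:
        X[:, p - config.n_constant:] = rng.uniform(-2.0, 2.0, size=config.n_constant)

    ids = _compound_ids(n)
    ref = config.reference_id
    if ref not in ids:
        ref = ids[0]
    X[ids.index(ref), :k] = 0.0

    names = [f"D{j + 1:04d}" for j in range(p)]
    matrix = pd.DataFrame(X, index=pd.Index(ids, name="compound_id"), columns=names)

    beta_base = np.zeros(p)
    beta_base[:k] = config.coefficient_scale
    coeffs = {(s, m): _MARKER_SIGN[m] * beta_base for s in TEST_SYSTEMS for m in MARKERS}
    truth = GroundTruth(coefficients=coeffs, reference_compound_id=ref,
                        informative_indices=list(range(k)), descriptor_names=names)
    return matrix, truth


def generate_response_studies(descriptors: pd.DataFrame, truth: GroundTruth,
                              config: GeneratorConfig) -> pd.DataFrame:
    """Simulate per-study raw cytokine measurements.

    Each generated study measures the reference compound (noise-free, by the
    ratio-scale noise convention) and one analogue at three doses; the
    analogue's raw value at a dose is
    ``exp(x·β) × baseline × dose_profile × lognormal(cv)``, with one noise
    draw per (study, analogue) so the analogue/reference ratio is constant
    across doses within a study.
    """
    config.validate()
    if truth.reference_compound_id not in descriptors.index:
        raise ValueError(
            f"reference compound {truth.reference_compound_id!r} missing from descriptors")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    cv = config.study_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    ref = truth.reference_compound_id
    analogues = np.array([c for c in descriptors.index if c != ref])
    X = descriptors.to_numpy(dtype=float)
    ana_pos = np.array([descriptors.index.get_loc(c) for c in analogues])
    frames: list[pd.DataFrame] = []
    study_counter = 0
    n_doses = len(DOSES)
    for system, marker in ((s, m) for s in config.systems for m in config.markers):
        beta = truth.coefficients[(system, marker)]
        mu = np.exp(X[ana_pos] @ beta)  # expected normalized response per analogue
        species, setting = system.split("/")[0], system.split("/")[1]
        presentation = system.split("/")[2] if setting == "in-vitro" else ""
        dose_unit = "µg/kg" if setting == "in-vivo" else "ng/mL"
        measured = rng.random(len(analogues)) < config.cell_prob(system, marker)
        n_studies = rng.integers(config.n_studies_min, config.n_studies_max + 1,
                                 size=len(analogues))
        n_studies = np.where(measured, n_studies, 0)
        total = int(n_studies.sum())
        if total == 0:
            continue
        # one row group per (study, dose) pair, reference + analogue
        cid_rep = np.repeat(analogues, n_studies)
        mu_rep = np.repeat(mu, n_studies)
        sids = np.array([f"S{study_counter + i + 1:06d}" for i in range(total)])
        study_counter += total
        noise = (np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=total))
                 if sigma else np.ones(total))
        dose_arr = np.tile(np.asarray(DOSES), total)
        prof_arr = np.tile(np.asarray(REFERENCE_DOSE_PROFILE), total)
        ref_raw = REFERENCE_BASELINE * prof_arr
        ana_val = np.repeat(mu_rep * noise, n_doses) * ref_raw
        half = pd.DataFrame({
            "study_id": np.repeat(sids, n_doses), "dose": dose_arr,
            "ref_value": ref_raw, "ana_value": ana_val,
            "compound_id": np.repeat(cid_rep, n_doses)})
        for which, col in (("ref", "ref_value"), ("ana", "ana_value")):
            part = pd.DataFrame({
                "compound_id": ref if which == "ref" else half["compound_id"],
                "study_id": half["study_id"], "species": species,
                "setting": setting, "presentation": presentation, "marker": marker,
                "dose": half["dose"], "dose_unit": dose_unit, "time": 24.0,
                "time_unit": "h", "value": half[col]})
            frames.append(part)
    if not frames:
        return pd.DataFrame(columns=[
            "compound_id", "study_id", "species", "setting", "presentation",
            "marker", "dose", "dose_unit", "time", "time_unit", "value"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["marker", "study_id", "dose", "compound_id"],
                           kind="mergesort").reset_index(drop=True)


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience: descriptor matrix, response records and truth in one call."""
    descriptors, truth = generate_chemical_space(config)
    records = generate_response_studies(descriptors, truth, config)
    return descriptors, records, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixture_suite(out_dir, seed: int = 0,
                           config: GeneratorConfig | None = None) -> dict:
    """Write a small self-contained fixture set and return its manifest.

    Files: ``descriptors.csv``, ``responses.csv``, ``ground_truth.json`` and
    ``assay_counts.csv`` (the packaged literature assay-frequency fixture).
    The manifest lists each file with a SHA-256 checksum; identical seeds
    give identical checksums.
    """
    from .dataset import LITERATURE_ASSAY_COUNTS  # deferred: avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = GeneratorConfig(n_compounds=50, n_descriptors=25, n_informative=5,
                                 n_constant=3, seed=seed)
    else:
        config = GeneratorConfig(**{**config.__dict__, "seed": seed})
    descriptors, records, truth = generate_dataset(config)

    files = {}
    p = out / "descriptors.csv"
    descriptors.to_csv(p, float_format="%.10g")
    files["descriptors.csv"] = _sha256(p)
    p = out / "responses.csv"
    records.to_csv(p, index=False, float_format="%.10g")
    files["responses.csv"] = _sha256(p)
    p = out / "ground_truth.json"
    p.write_text(truth.to_json(), encoding="utf-8")
    files["ground_truth.json"] = _sha256(p)
    p = out / "assay_counts.csv"
    counts = pd.DataFrame(
        [(s, m, c) for (s, m), c in LITERATURE_ASSAY_COUNTS.items()],
        columns=["test_system", "marker", "count"])
    counts.to_csv(p, index=False)
    files["assay_counts.csv"] = _sha256(p)

    manifest = {"seed": int(seed), "n_compounds": config.n_compounds, "files": files}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
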