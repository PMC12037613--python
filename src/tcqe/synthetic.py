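"""Seeded generators emulating every input the pipeline consumes.

Each generator is a pure function of its spec (which includes the seed)
and records the ground truth needed to score the downstream screens:

* :func:`gen_network` — compound / prediction / disease-gene tables with
  OB-DL scores straddling the compound gate, prediction probabilities
  straddling 0.1, relevance scores straddling their median, and planted
  hub targets wired densely enough to dominate the topological screen;
* :func:`gen_feature_table` — lognormal feature intensities with planted
  fold changes in one group, multiplicative injection-order drift, and
  pooled QC injections interleaved at a fixed interval;
* :func:`gen_assay` — plate signals back-computed from probit-linear
  dose-inhibition curves with known relative potencies and Gaussian
  noise on the probit scale (conjugate to the probit-line estimator
  while still exercising the readings-to-inhibition path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .biopotency import design_dilution_series
from .errors import ValidationError

# ---------------------------------------------------------------------------
# network arm


@dataclass
class NetworkSimSpec:
    n_compounds: int = 20
    n_targets: int = 40
    n_disease_genes: int = 30
    overlap_fraction: float = 0.5    # fraction of screened disease genes
    planted_hubs: list[tuple[str, float]] = field(
        default_factory=lambda: [("HUB1", 0.8)]
    )                                 # (target id, fraction of active compounds wired)
    compound_pass_fraction: float = 0.5
    edge_probability: float = 0.15    # kept for the spec surface; background
    seed: int = 0                     # degrees are drawn 1-3 regardless

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction <= 1:
            raise ValidationError("overlap_fraction must lie in [0, 1]")
        for hub, frac in self.planted_hubs:
            if math_ceil(frac * self.n_compounds * self.compound_pass_fraction) < 4:
                raise ValidationError(
                    f"hub {hub}: degree boost {frac} infeasible for "
                    f"{self.n_compounds} compounds"
                )


def math_ceil(x: float) -> int:
    return int(np.ceil(x))


def gen_network(spec: NetworkSimSpec, outdir: str | Path | None = None):
    """Generate the three network-arm tables plus ground truth.

    Returns (compounds, predictions, disease_genes, ground_truth); when
    ``outdir`` is given also writes compounds.csv, predictions.csv,
    disease_genes.csv and ground_truth.json.
    """
    rng = np.random.default_rng(spec.seed)
    n_pass = max(2, round(spec.n_compounds * spec.compound_pass_fraction))

    comp_ids = [f"C{i:03d}" for i in range(spec.n_compounds)]
    passing = set(comp_ids[:n_pass])
    rows = []
    for cid in comp_ids:
        if cid in passing:
            ob = float(rng.uniform(30.0, 80.0))
            dl = float(rng.uniform(0.18, 0.9))
        else:
            # fail at least one side of the OB/DL gate
            if rng.random() < 0.5:
                ob, dl = float(rng.uniform(1.0, 29.9)), float(rng.uniform(0.01, 0.9))
            else:
                ob, dl = float(rng.uniform(30.0, 80.0)), float(rng.uniform(0.01, 0.17))
        rows.append({"id": cid, "name": f"compound-{cid}", "ob": ob, "dl": dl})
    compounds = pd.DataFrame(rows)

    hub_ids = [h for h, _ in spec.planted_hubs]
    background = [f"T{i:03d}" for i in range(spec.n_targets - len(hub_ids))]
    target_ids = hub_ids + background
    active = sorted(passing)

    pred_rows = []
    hub_partner_count: dict[str, int] = {}
    for hub, frac in spec.planted_hubs:
        k = math_ceil(frac * len(active))
        partners = list(rng.choice(active, size=k, replace=False))
        hub_partner_count[hub] = k
        for c in partners:
            pred_rows.append(
                {"compound_id": c, "target_id": hub,
                 "probability": float(rng.uniform(0.15, 0.6))}
            )
    for t in background:
        k = int(rng.integers(1, 4))   # background degree 1-3, below the screen
        partners = list(rng.choice(active, size=min(k, len(active)), replace=False))
        for c in partners:
            pred_rows.append(
                {"compound_id": c, "target_id": t,
                 "probability": float(rng.uniform(0.15, 0.6))}
            )
    # sub-threshold predictions from non-passing compounds and weak scores:
    # probabilities straddle the 0.1 gate
    for t in rng.choice(background, size=max(1, len(background) // 3), replace=False):
        c = comp_ids[int(rng.integers(0, spec.n_compounds))]
        pred_rows.append(
            {"compound_id": c, "target_id": str(t),
             "probability": float(rng.uniform(0.01, 0.1))}
        )
    predictions = pd.DataFrame(pred_rows)

    # disease genes: relevance straddles the median; the top half overlaps
    # predicted targets at overlap_fraction
    n_dg = spec.n_disease_genes
    relevance = np.sort(rng.uniform(0.5, 40.0, size=n_dg))[::-1]
    n_screened = int(np.sum(relevance > np.median(relevance)))
    n_overlap = round(spec.overlap_fraction * n_screened)
    predicted_targets = list(dict.fromkeys([r["target_id"] for r in pred_rows]))
    # hubs overlap first so they become common targets
    overlap_pool = hub_ids + [t for t in predicted_targets if t not in hub_ids]
    overlap_ids = overlap_pool[:n_overlap]
    dg_rows = []
    extra = 0
    for i in range(n_dg):
        if i < len(overlap_ids):
            gid = overlap_ids[i]
        else:
            gid = f"D{extra:03d}"
            extra += 1
        dg_rows.append({"gene_id": gid, "relevance": float(relevance[i])})
    disease_genes = pd.DataFrame(dg_rows)

    median_rel = float(np.median(relevance))
    truth = {
        "seed": spec.seed,
        "compounds_passing": sorted(passing),
        "predictions_passing": sorted(
            {(r["compound_id"], r["target_id"]) for r in pred_rows
             if r["probability"] > 0.1},
        ),
        "disease_genes_screened": [
            r["gene_id"] for r in dg_rows if r["relevance"] > median_rel
        ],
        "planted_hubs": hub_ids,
        "hub_degrees": hub_partner_count,
    }
    truth["predictions_passing"] = [list(t) for t in truth["predictions_passing"]]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        compounds.to_csv(outdir / "compounds.csv", index=False, lineterminator="\n")
        predictions.to_csv(outdir / "predictions.csv", index=False, lineterminator="\n")
        disease_genes.to_csv(
            outdir / "disease_genes.csv", index=False, lineterminator="\n"
        )
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return compounds, predictions, disease_genes, truth


# ---------------------------------------------------------------------------
# metabolomics arm


@dataclass
class MetaboSimSpec:
    n_features: int = 100
    n_per_group: int = 8
    groups: tuple[str, str] = ("control", "model")
    n_qc: int = 5
    qc_interval: int = 4
    planted_effects: list[tuple[int, float]] = field(
        default_factory=lambda: [(i, 2.0) for i in range(20)]
    )                                # (feature index, fold change in group B)
    base_log_mean: float = 11.5      # lognormal location of feature means
    base_log_sigma: float = 1.0
    replicate_cv: float = 0.2        # multiplicative noise CV
    drift_model: str = "linear"      # or "sinusoidal"
    drift_coefficient: float = 0.0   # per-injection fractional drift
    seed: int = 0

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.planted_effects]
        if len(idx) != len(set(idx)):
            raise ValidationError("planted feature indices must be distinct")
        if any(i >= self.n_features for i in idx):
            raise ValidationError("planted feature index out of range")
        if self.replicate_cv <= 0:
            raise ValidationError("replicate_cv must be positive")
        if self.drift_model not in {"linear", "sinusoidal"}:
            raise ValidationError(f"unknown drift model {self.drift_model!r}")


def _drift_factor(spec: MetaboSimSpec, order: np.ndarray) -> np.ndarray:
    if spec.drift_coefficient == 0.0:
        return np.ones_like(order, dtype=float)
    if spec.drift_model == "linear":
        return 1.0 + spec.drift_coefficient * order
    return 1.0 + spec.drift_coefficient * np.sin(
        2.0 * np.pi * order / max(order.max(), 1.0)
    )


def gen_feature_table(spec: MetaboSimSpec, outdir: str | Path | None = None):
    """Generate a features x samples table with planted effects and drift.

    Biological samples of the two groups alternate in the injection
    sequence with a pooled QC injected every ``qc_interval`` runs (plus
    lead-in and tail QCs).  Returns (intensities, samples, ground_truth).
    """
    from .metabolomics import FeatureTable

    rng = np.random.default_rng(spec.seed)
    n_bio = 2 * spec.n_per_group
    g_a, g_b = spec.groups

    # feature-level true means and the planted group-B fold changes
    base = rng.lognormal(spec.base_log_mean, spec.base_log_sigma, size=spec.n_features)
    fold = np.ones(spec.n_features)
    for idx, fc in spec.planted_effects:
        fold[idx] = fc

    sample_ids = [f"{g_a}{i + 1}" for i in range(spec.n_per_group)] + [
        f"{g_b}{i + 1}" for i in range(spec.n_per_group)
    ]
    bio_order = rng.permutation(n_bio)   # randomised run order

    # build the injection sequence: QC first, then every qc_interval runs
    seq: list[tuple[str, str, bool]] = []   # (sample id, group, is_qc)
    qc_count = 0
    next_bio = 0
    while next_bio < n_bio or qc_count < spec.n_qc:
        if (len(seq) % (spec.qc_interval + 1) == 0 and qc_count < spec.n_qc) or (
            next_bio >= n_bio
        ):
            qc_count += 1
            seq.append((f"QC{qc_count}", "QC", True))
        else:
            sid = sample_ids[bio_order[next_bio]]
            group = g_a if sid.startswith(g_a) else g_b
            seq.append((sid, group, False))
            next_bio += 1

    sigma_log = float(np.sqrt(np.log1p(spec.replicate_cv**2)))
    orders = np.arange(1, len(seq) + 1, dtype=float)
    drift = _drift_factor(spec, orders)

    cols = {}
    for pos, (sid, group, is_qc) in enumerate(seq):
        if is_qc:
            true_mean = base * (fold + 1.0) / 2.0  # pooled across groups
        elif group == g_b:
            true_mean = base * fold
        else:
            true_mean = base
        noise = rng.lognormal(-0.5 * sigma_log**2, sigma_log, size=spec.n_features)
        cols[sid] = true_mean * noise * drift[pos]

    feature_ids = [f"F{i:04d}" for i in range(spec.n_features)]
    intensities = pd.DataFrame(cols, index=feature_ids)
    samples = pd.DataFrame(
        {
            "group": [g for _, g, _ in seq],
            "is_qc": [q for _, _, q in seq],
            "injection_order": np.arange(1, len(seq) + 1),
        },
        index=[s for s, _, _ in seq],
    )
    samples.index.name = "sample_id"

    truth = {
        "seed": spec.seed,
        "planted_features": [feature_ids[i] for i, _ in spec.planted_effects],
        "fold_changes": {feature_ids[i]: fc for i, fc in spec.planted_effects},
        "drift_model": spec.drift_model,
        "drift_coefficient": spec.drift_coefficient,
        "groups": list(spec.groups),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        intensities.rename_axis("feature_id").to_csv(
            outdir / "features.csv", lineterminator="\n"
        )
        samples.to_csv(outdir / "samples.csv", lineterminator="\n")
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return FeatureTable(intensities, samples), truth


# ---------------------------------------------------------------------------
# biopotency arm


@dataclass
class AssaySimSpec:
    true_relative_potencies: dict[str, float] = field(
        default_factory=lambda: {"S2": 0.5}
    )                                # batch -> true R vs reference
    reference_batch: str = "S1"
    reference_ed50: float = 2.0      # dose units (e.g. ug/mL)
    slope: float = 2.0               # probit units per log10 dose
    top_dose: float = 8.0
    n_doses: int = 4
    dilution_ratio: float = 0.5
    replicates: int = 3
    probit_noise_sd: float = 0.1
    control_signal: float = 100.0
    blank_signal: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.true_relative_potencies.values()):
            raise ValidationError("relative potencies must be positive")
        if self.reference_ed50 <= 0 or self.top_dose <= 0:
            raise ValidationError("doses must be positive")


def gen_assay(spec: AssaySimSpec, outdir: str | Path | None = None):
    """Generate a long-format plate table from probit-linear truth.

    Per batch, true inhibition at dose d is
    Phi(slope * (log10 d - log10 ED50_batch)) with
    ED50_batch = reference ED50 / R; Gaussian noise with sd
    ``probit_noise_sd`` is added on the probit scale per replicate, and
    signals are back-computed through the plate formula
    signal = blank + (control - blank) * (1 - inhibition).

    Returns (plate DataFrame, ground_truth dict).
    """
    rng = np.random.default_rng(spec.seed)
    doses = design_dilution_series(spec.top_dose, spec.n_doses, spec.dilution_ratio)
    batches = {spec.reference_batch: 1.0, **spec.true_relative_potencies}

    rows = []
    for batch, r_true in batches.items():
        ed50 = spec.reference_ed50 / r_true
        for dose in doses:
            z_true = spec.slope * (np.log10(dose) - np.log10(ed50))
            for rep in range(1, spec.replicates + 1):
                z = z_true + (
                    rng.normal(0.0, spec.probit_noise_sd)
                    if spec.probit_noise_sd > 0
                    else 0.0
                )
                inhibition = float(stats.norm.cdf(z))
                signal = spec.blank_signal + (
                    spec.control_signal - spec.blank_signal
                ) * (1.0 - inhibition)
                rows.append(
                    {
                        "batch": batch,
                        "dose": dose,
                        "replicate": f"r{rep}",
                        "signal": signal,
                        "well_role": "sample",
                    }
                )
    for rep in range(1, spec.replicates + 1):
        rows.append({"batch": "plate", "dose": 0.0, "replicate": f"r{rep}",
                     "signal": spec.control_signal, "well_role": "control"})
        rows.append({"batch": "plate", "dose": 0.0, "replicate": f"r{rep}",
                     "signal": spec.blank_signal, "well_role": "blank"})
    plate = pd.DataFrame(rows)

    truth = {
        "seed": spec.seed,
        "reference_batch": spec.reference_batch,
        "reference_ed50": spec.reference_ed50,
        "slope": spec.slope,
        "true_relative_potencies": dict(batches),
        "doses": doses,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        plate.to_csv(outdir / "plate.csv", index=False, lineterminator="\n")
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return plate, truth
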