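"""Survey statistics: counts, frequency tables and histograms.

Aggregates the per-contact tables produced by the survey into the
report quantities of interest: how many structures contain each contact
family, per-structure contact-count distributions, frequencies by
nucleobase / amino acid / tilt category / edge role / sugar edge class
and atom-label set, and tilt (5 degree bins) and closest-distance
(0.1 A bins) histograms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["SurveyReport", "aggregate", "histogram", "percentages"]


def histogram(values, bin_width: float, domain: tuple[float, float]):
    """Bin values into half-open bins [lo, lo+w) covering ``domain``;
    the last bin is closed.  Values outside the domain are an error.

    Returns ``(edges, counts)`` with ``len(edges) = len(counts) + 1``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = domain
    values = np.asarray(list(values), dtype=float)
    offenders = values[(values < lo) | (values > hi)]
    if offenders.size:
        raise ValueError(f"values outside domain {domain}: "
                         f"{sorted(offenders.tolist())}")
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9)) or 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def percentages(counts: dict, decimals: int = 1) -> dict:
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


@dataclass
class SurveyReport:
    """Aggregated survey statistics for one contact table."""

    n_structures_searched: int
    n_with_pi_pi: int
    n_with_sugar_pi: int
    n_with_none: int
    total_pi_pi: int
    total_sugar_pi: int
    contacts_per_structure: dict = field(default_factory=dict)
    by_base: dict = field(default_factory=dict)
    by_amino_acid: dict = field(default_factory=dict)
    by_base_aa_pair: dict = field(default_factory=dict)
    by_tilt_category: dict = field(default_factory=dict)
    by_edge_role: dict = field(default_factory=dict)
    by_sugar_class: dict = field(default_factory=dict)
    by_sugar_labels: dict = field(default_factory=dict)
    sugar_by_amino_acid: dict = field(default_factory=dict)
    tilt_histogram: dict = field(default_factory=dict)
    distance_histogram: dict = field(default_factory=dict)
    by_protein_class: dict = field(default_factory=dict)

    @property
    def total_contacts(self) -> int:
        return self.total_pi_pi + self.total_sugar_pi

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total_contacts"] = self.total_contacts
        d["percent_by_tilt_category"] = percentages(self.by_tilt_category)
        d["percent_by_sugar_class"] = percentages(self.by_sugar_class)
        d["percent_by_base"] = percentages(self.by_base)
        d["percent_by_amino_acid"] = percentages(self.by_amino_acid)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _hist_dict(values, bin_width, domain) -> dict:
    if len(values) == 0:
        return {}
    edges, counts = histogram(values, bin_width, domain)
    return {f"[{edges[i]:g},{edges[i + 1]:g})": int(c)
            for i, c in enumerate(counts) if c > 0}


def aggregate(contacts: pd.DataFrame, entry_ids=None,
              manifest: pd.DataFrame | None = None) -> SurveyReport:
    """Aggregate a contact table into a :class:`SurveyReport`.

    ``contacts`` is the table from the survey (one row per candidate,
    valid and rejected); only valid contacts are counted.  ``entry_ids``
    lists every structure searched (structures without any contact do
    not appear in the table); defaults to the entry IDs present.
    ``manifest`` may carry ``entry_id`` and ``protein_class`` columns
    for the optional protein-class breakdown.
    """
    valid = contacts[contacts["valid"]].copy() if len(contacts) else contacts
    pi = valid[valid["contact_type"] == "pi_pi"] if len(valid) else valid
    sugar = valid[valid["contact_type"] == "sugar_pi"] if len(valid) else valid

    if entry_ids is None:
        entry_ids = sorted(contacts["entry_id"].unique()) if len(contacts) else []
    entry_ids = list(entry_ids)
    with_pi = set(pi["entry_id"]) if len(pi) else set()
    with_sugar = set(sugar["entry_id"]) if len(sugar) else set()

    def counts(series) -> dict:
        if len(series) == 0:
            return {}
        return {str(k): int(v) for k, v in series.value_counts().sort_index().items()}

    per_structure = {}
    if len(valid):
        vc = valid.groupby("entry_id").size()
        for n, c in vc.value_counts().sort_index().items():
            per_structure[int(n)] = int(c)

    by_pair = {}
    if len(pi):
        pair = pi["base_or_sugar_resname"] + ":" + pi["aa_resname"]
        by_pair = counts(pair)

    by_protein_class = {}
    if manifest is not None and "protein_class" in manifest.columns and len(valid):
        merged = valid.merge(manifest[["entry_id", "protein_class"]],
                             on="entry_id", how="left")
        by_protein_class = counts(merged["protein_class"].fillna("unknown"))

    report = SurveyReport(
        n_structures_searched=len(entry_ids),
        n_with_pi_pi=len(with_pi),
        n_with_sugar_pi=len(with_sugar),
        n_with_none=len([e for e in entry_ids
                         if e not in with_pi and e not in with_sugar]),
        total_pi_pi=int(len(pi)),
        total_sugar_pi=int(len(sugar)),
        contacts_per_structure=per_structure,
        by_base=counts(pi["base_or_sugar_resname"]) if len(pi) else {},
        by_amino_acid=counts(pi["aa_resname"]) if len(pi) else {},
        by_base_aa_pair=by_pair,
        by_tilt_category=counts(pi["category"]) if len(pi) else {},
        by_edge_role=counts(pi["edge_role_or_atom_labels"]) if len(pi) else {},
        by_sugar_class=counts(sugar["category"]) if len(sugar) else {},
        by_sugar_labels=counts(sugar["edge_role_or_atom_labels"])
        if len(sugar) else {},
        sugar_by_amino_acid=counts(sugar["aa_resname"]) if len(sugar) else {},
        tilt_histogram=_hist_dict(pi["omega_deg"].dropna().to_numpy()
                                  if len(pi) else [], 5.0, (0.0, 90.0)),
        distance_histogram=_hist_dict(
            valid["d_min_angstrom"].dropna().to_numpy() if len(valid) else [],
            0.1, (0.0, 10.0)),
        by_protein_class=by_protein_class,
    )
    return report


def plot_report(report: SurveyReport, out_dir) -> list:
    """Write tilt/distance histogram and frequency-bar plots as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def bar(data: dict, title: str, fname: str, xlabel: str):
        if not data:
            return
        fig, ax = plt.subplots(figsize=(6, 3.5))
        keys = list(data)
        ax.bar(range(len(keys)), [data[k] for k in keys], color="#4878d0")
        ax.set_xticks(range(len(keys)))
        ax.set_xticklabels(keys, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("count")
        ax.set_xlabel(xlabel)
        ax.set_title(title)
        fig.tight_layout()
        p = out_dir / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    bar(report.tilt_histogram, "Tilt angle distribution", "tilt_histogram.png",
        "omega (deg)")
    bar(report.distance_histogram, "Closest heavy-atom distance",
        "distance_histogram.png", "d_min (A)")
    bar(report.by_tilt_category, "pi-pi categories", "tilt_categories.png", "")
    bar(report.by_sugar_class, "Sugar-pi edge classes", "sugar_classes.png", "")
    bar(report.by_base, "pi-pi contacts by nucleobase", "by_base.png", "")
    bar(report.by_amino_acid, "pi-pi contacts by amino acid",
        "by_amino_acid.png", "")
    return written
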