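"""Packaged comparative physiology dataset of Saccharomycetaceae yeasts.

The package ships a strain-level table of aerobic batch-culture metrics
(ethanol and biomass yields on glucose, specific glucose-consumption and
ethanol-production rates, and maximum specific growth rate) for 66
cultivation runs covering twelve Saccharomycetaceae genera plus five
non-Saccharomycetaceae control species.  This module loads that table,
averages biological replicates, applies the exclusion rules used in the
comparative analysis (the fructophilic *Zygosaccharomyces* genus, the
cockroach-gut isolate *Tetrapisispora blattae*, and the control clades),
and assigns each strain to one of four phylogenetic groups anchored on
the whole-genome-duplication (WGD) event:

* group 1 — *Kluyveromyces* and *Eremothecium* (Crabtree-negative clade),
* group 2 — *Lachancea*, *Torulaspora*, *Zygotorulaspora* (non-WGD,
  intermediate fermenters),
* group 3 — *Vanderwaltozyma* and *Tetrapisispora* (early post-WGD),
* group 4 — *Saccharomyces*, *Kazachstania*, *Naumovozyma*,
  *Nakaseomyces* (post-WGD, strongly Crabtree-positive).

Two rows of the printed table are internally inconsistent (they violate
the table-wide identity mu ~= q_S * Y_X/S that every other row obeys):
the *Kaz. exiguus* row looks column-shifted and the *Tor. franciscae*
rows have their consumption and production rates swapped.  The default
loader returns the table exactly as printed; ``repaired=True`` applies
the reconstruction documented in :data:`REPAIRS`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "SpeciesRecord",
    "GENUS_CODES",
    "GROUP_BY_GENUS",
    "NUMERIC_FIELDS",
    "REPAIRS",
    "load_reference_table",
    "build_analysis_set",
    "assign_phylo_group",
    "analysis_frame",
    "packaged_table_path",
]

#: The 16 genus prefixes that occur in the reference table.
GENUS_CODES = frozenset(
    {"Sac", "Kaz", "Nau", "Nak", "Tet", "Van", "Zsa", "Zto",
     "Tor", "Lac", "Klu", "Ere", "Deb", "Dek", "Pic", "Sch"}
)

#: Phylogenetic group per genus; ``None`` marks excluded/control clades.
GROUP_BY_GENUS: dict[str, Optional[int]] = {
    "Klu": 1, "Ere": 1,
    "Lac": 2, "Tor": 2, "Zto": 2,
    "Van": 3, "Tet": 3,
    "Sac": 4, "Kaz": 4, "Nau": 4, "Nak": 4,
    "Zsa": None, "Deb": None, "Dek": None, "Pic": None, "Sch": None,
}

NUMERIC_FIELDS = (
    "ethanol_yield",
    "biomass_yield",
    "glc_cons_rate",
    "etoh_prod_rate",
    "growth_rate",
)

_EXPECTED_COLUMNS = (
    "species", "y_collection", "cbs", "other",
) + NUMERIC_FIELDS

#: Reconstruction of the two internally inconsistent printed rows,
#: keyed by species label.  Tor. franciscae: consumption and production
#: rates swapped back.  Kaz. exiguus: the printed row is read as a
#: one-column shift — true (Y_E/S, Y_X/S, q_S, q_E) = (0.43, 0.18,
#: 1.75, 0.74) — and the growth rate lost in the shift is reconstructed
#: from the table-wide identity mu = q_S * Y_X/S = 0.315.
REPAIRS: dict[str, dict[str, float]] = {
    "Tor. franciscae A2": {"glc_cons_rate": 0.95, "etoh_prod_rate": 0.27},
    "Tor. franciscae A1": {"glc_cons_rate": 1.03, "etoh_prod_rate": 0.25},
    "Kaz. exiguus": {
        "ethanol_yield": 0.43,
        "biomass_yield": 0.18,
        "glc_cons_rate": 1.75,
        "etoh_prod_rate": 0.74,
        "growth_rate": 0.315,
    },
}

_REPLICATE_RE = re.compile(r"\s[AB][12]$")


@dataclass(frozen=True)
class SpeciesRecord:
    """One cultivation run (or replicate-averaged strain) of the table."""

    species_label: str
    strain_key: str
    genus_code: str
    ethanol_yield: float      # g ethanol / g glucose
    biomass_yield: float      # g dry weight / g glucose
    glc_cons_rate: float      # g glucose / gDW / h
    etoh_prod_rate: float     # g ethanol / gDW / h
    growth_rate: float        # 1/h
    collection_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.genus_code not in GENUS_CODES:
            raise ValueError(
                f"unknown genus code {self.genus_code!r} "
                f"for {self.species_label!r}"
            )
        for field in NUMERIC_FIELDS:
            value = getattr(self, field)
            if not (value >= 0.0):
                raise ValueError(
                    f"{field} must be >= 0 for {self.species_label!r}, "
                    f"got {value!r}"
                )


def packaged_table_path() -> Path:
    """Filesystem path of the packaged reference table."""
    return Path(resources.files("crabtree").joinpath("data/table1.tsv"))


def _strain_key(species_label: str, collection_ids: Sequence[str]) -> str:
    """Species label with the replicate token stripped, plus the first
    collection id (needed because two *L. kluyverii* strains share the
    species name)."""
    base = _REPLICATE_RE.sub("", species_label)
    primary = collection_ids[0] if collection_ids else ""
    return f"{base}|{primary}"


def load_reference_table(
    path: str | Path | None = None, *, repaired: bool = False
) -> list[SpeciesRecord]:
    """Load the reference table (or a user TSV in the same layout).

    Parameters
    ----------
    path
        TSV file with one row per cultivation run.  ``None`` loads the
        packaged table.
    repaired
        Apply :data:`REPAIRS` to the two internally inconsistent printed
        rows.  Default is the table exactly as printed.

    Returns
    -------
    list of :class:`SpeciesRecord`, one per row, in file order.
    """
    path = packaged_table_path() if path is None else Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse reference table {path}: {exc}") from exc

    missing = [c for c in _EXPECTED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"reference table {path} is missing columns: {', '.join(missing)}"
        )

    records: list[SpeciesRecord] = []
    for idx, row in frame.iterrows():
        label = str(row["species"]).strip()
        values: dict[str, float] = {}
        for field in NUMERIC_FIELDS:
            raw = row[field]
            try:
                values[field] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {idx + 2} ({label!r}): cannot parse "
                    f"{field}={raw!r}"
                ) from None
        if repaired and label in REPAIRS:
            values.update(REPAIRS[label])
        collection_ids = tuple(
            str(row[c]).strip()
            for c in ("y_collection", "cbs", "other")
            if pd.notna(row[c]) and str(row[c]).strip()
        )
        records.append(
            SpeciesRecord(
                species_label=label,
                strain_key=_strain_key(label, collection_ids),
                genus_code=label.split(".", 1)[0],
                collection_ids=collection_ids,
                **values,
            )
        )
    return records


def _is_excluded(record: SpeciesRecord) -> bool:
    """Exclusion rules of the comparative analysis.

    *Zygosaccharomyces* is fructophilic (cultivated on glucose it is not
    comparable), *T. blattae* is a gut isolate grown with supplements,
    and the five non-Saccharomycetaceae species are controls.
    """
    if record.genus_code in {"Zsa", "Deb", "Dek", "Pic", "Sch"}:
        return True
    return record.strain_key.startswith("Tet. blattae|")


def build_analysis_set(records: Iterable[SpeciesRecord]) -> list[SpeciesRecord]:
    """Collapse replicates and apply exclusions; returns one record per
    analysis strain (37 for the packaged table).

    Replicate runs (``A1``/``A2`` or ``B1``/``B2`` suffixes) of the same
    strain are replaced by the per-metric arithmetic mean of run-level
    values.  The operation is idempotent: averaged records pass through
    unchanged.
    """
    kept = [r for r in records if not _is_excluded(r)]
    by_key: dict[str, list[SpeciesRecord]] = {}
    for record in kept:
        by_key.setdefault(record.strain_key, []).append(record)

    out: list[SpeciesRecord] = []
    for key, group in by_key.items():
        if len(group) == 1:
            record = group[0]
            if _REPLICATE_RE.search(record.species_label):
                record = replace(
                    record,
                    species_label=_REPLICATE_RE.sub("", record.species_label),
                )
            out.append(record)
            continue
        if len(group) > 2:
            warnings.warn(
                f"{key!r} has {len(group)} replicate runs; averaging all",
                stacklevel=2,
            )
        means = {
            field: sum(getattr(r, field) for r in group) / len(group)
            for field in NUMERIC_FIELDS
        }
        ids: list[str] = []
        for r in group:
            for cid in r.collection_ids:
                if cid not in ids:
                    ids.append(cid)
        out.append(
            SpeciesRecord(
                species_label=_REPLICATE_RE.sub("", group[0].species_label),
                strain_key=key,
                genus_code=group[0].genus_code,
                collection_ids=tuple(ids),
                **means,
            )
        )
    return out


def assign_phylo_group(
    genus_code: str, species_label: str = ""
) -> Optional[int]:
    """Phylogenetic group (1-4) for a genus code, or ``None`` for
    excluded/control clades."""
    try:
        return GROUP_BY_GENUS[genus_code]
    except KeyError:
        raise ValueError(f"unknown genus code {genus_code!r}") from None


def analysis_frame(records: Iterable[SpeciesRecord]) -> pd.DataFrame:
    """Analysis set as a DataFrame with a ``group`` column (grouped
    strains only)."""
    rows = []
    for r in records:
        group = assign_phylo_group(r.genus_code, r.species_label)
        if group is None:
            continue
        rows.append(
            {
                "species": r.species_label,
                "strain_key": r.strain_key,
                "genus": r.genus_code,
                "group": group,
                **{f: getattr(r, f) for f in NUMERIC_FIELDS},
            }
        )
    return pd.DataFrame(rows)
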