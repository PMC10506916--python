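"""Neuron-specific enolase (NSE) concentration tables and site contrasts.

NSE is a neuronal enzyme used as a blood/tissue injury biomarker.  The
packaged tables hold the serum timeline (per swine group and timepoint)
and the tissue concentrations at sacrifice (impact site vs normal
cortex) for three animals: an unstimulated control, a swine stimulated
from postoperative day 2 (delayed), and a swine stimulated 20 minutes
after injury (immediate).

Serum cells that were blank in the source assay sheets are simply absent
(never imputed as zero), and negative serum values -- assay artifacts --
are preserved as recorded, flagged by ``valid = False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

GROUPS = ("control", "delayed_stimulation", "immediate_stimulation")
SERUM_CONTEXTS = (
    "pre_cci",
    "post_cci",
    "postop_day_2",
    "postop_day_7_10",
    "sacrifice_day_21",
)
TISSUE_CONTEXTS = ("impact_site", "normal_cortex")


@dataclass(frozen=True)
class NSERecord:
    swine_group: str
    context_type: str  # "serum" or "tissue"
    context: str
    concentration: float  # ng/mL

    @property
    def valid(self) -> bool:
        """False for physically impossible (negative) assay readings."""
        return self.concentration >= 0


def _read(name: str) -> pd.DataFrame:
    with resources.files("cortemf.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_nse() -> list[NSERecord]:
    """Every non-blank cell of the serum and tissue tables, exactly once."""
    records: list[NSERecord] = []
    for name, ctype, contexts in (
        ("nse_serum.csv", "serum", SERUM_CONTEXTS),
        ("nse_tissue.csv", "tissue", TISSUE_CONTEXTS),
    ):
        df = _read(name)
        for row in df.itertuples(index=False):
            if row.swine_group not in GROUPS:
                raise ValueError(f"unknown swine group {row.swine_group!r} in {name}")
            if row.context not in contexts:
                raise ValueError(f"unknown context {row.context!r} in {name}")
            records.append(
                NSERecord(row.swine_group, ctype, row.context, float(row.concentration_ng_ml))
            )
    return records


def load_nse_frame() -> pd.DataFrame:
    """The same records as a tidy DataFrame."""
    recs = load_nse()
    return pd.DataFrame(
        {
            "swine_group": [r.swine_group for r in recs],
            "context_type": [r.context_type for r in recs],
            "context": [r.context for r in recs],
            "concentration_ng_ml": [r.concentration for r in recs],
            "valid": [r.valid for r in recs],
        }
    )


def nse_value(group: str, context: str) -> float:
    """Concentration (ng/mL) for one group/context cell.

    Raises ``KeyError`` for unknown labels or blank cells.
    """
    if group not in GROUPS:
        raise KeyError(f"unknown swine group {group!r}; expected one of {GROUPS}")
    if context not in SERUM_CONTEXTS + TISSUE_CONTEXTS:
        raise KeyError(f"unknown context {context!r}")
    for rec in load_nse():
        if rec.swine_group == group and rec.context == context:
            return rec.concentration
    raise KeyError(f"no recorded value for ({group}, {context})")


def nse_site_contrast(group: str) -> float:
    """Tissue NSE difference, impact site minus normal cortex (ng/mL).

    Positive values indicate NSE enrichment at the lesion relative to
    uninjured cortex.
    """
    return nse_value(group, "impact_site") - nse_value(group, "normal_cortex")
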