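"""Accessors for the small plain-text fixtures shipped with the package.

``load_substrate_utilization`` returns the published sole carbon/nitrogen
source utilization table for S. radiopugnans (28 carbon + 6 nitrogen
substrates) as phenotype records plus the published in-silico call column.
The exchange-reaction ids in the table are placeholders in BiGG style; they
are remappable when screening a model whose namespace differs.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Optional

from gsmm.io import PhenotypeRecord, _CALL_SYMBOLS


def _data_path(name: str):
    return resources.files("gsmm.data").joinpath(name)


def load_substrate_utilization(
    role: Optional[str] = None,
) -> tuple[list[PhenotypeRecord], list[str]]:
    """Packaged utilization table -> (records, published in-silico calls).

    ``role`` filters to "carbon" or "nitrogen"; by default all 34 rows are
    returned in table order.
    """
    records: list[PhenotypeRecord] = []
    published: list[str] = []
    with _data_path("substrate_utilization.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if role is not None and row["role"] != role:
                continue
            records.append(
                PhenotypeRecord(
                    substrate=row["substrate"],
                    role=row["role"],
                    exchange_reaction_id=row["exchange_id"],
                    in_vivo=_CALL_SYMBOLS[row["in_vivo"].strip()],
                    reference=row["reference"],
                )
            )
            published.append(_CALL_SYMBOLS[row["in_silico_published"].strip()])
    return records, published


def phenotype_table_path():
    """Filesystem path of the packaged utilization TSV (for CLI defaults)."""
    return _data_path("substrate_utilization.tsv")
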