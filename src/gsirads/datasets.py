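"""Packaged reference data.

The ``contingency`` datasets are paired rater-agreement tables from a
published 1596-patient multicenter glioblastoma cohort in which every
tumor was segmented both by a trained human rater (rater A) and by an
automated segmentation model (rater B), and the categorical report
features were derived from both.  They serve as ground truth for the
agreement-statistics suite:

* ``laterality`` — left / right / none, 3x3
* ``contralateral_infiltration`` — no / yes, 2x2
* ``multifocality`` — no / yes, 2x2
* ``n_foci`` — number of tumor foci (ordinal counts); rater A observed
  classes up to 11 foci while rater B topped out at 5, so the table is
  squared over the union of observed classes with zero-padding.

Tables are stored as long CSV (rater_a, rater_b, count) and loaded into
:class:`~gsirads.agreement.PairedContingency`.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np

from .agreement import PairedContingency
from .errors import ValidationError

VALIDATION_TABLES = (
    "laterality",
    "contralateral_infiltration",
    "multifocality",
    "n_foci",
)


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s


def load_contingency_csv(path) -> PairedContingency:
    """Read a long-format contingency CSV (rater_a, rater_b, count).

    Classes are the union of labels seen in either column, in first-seen
    order for string labels and ascending order for integer labels.
    """
    with open(path, newline="") as f:
        reader = csv.reader(f)
        rows = list(reader)
    if rows and rows[0][0].strip().lower() in ("rater_a", "row", "a"):
        rows = rows[1:]
    cells = []
    for r in rows:
        if not r or not "".join(r).strip():
            continue
        if len(r) != 3:
            raise ValidationError(f"expected 3 columns, got {r!r}")
        cells.append((_maybe_int(r[0].strip()), _maybe_int(r[1].strip()), int(r[2])))
    labels: list = []
    for a, b, _ in cells:
        for lab in (a, b):
            if lab not in labels:
                labels.append(lab)
    if all(isinstance(lab, int) for lab in labels):
        labels = sorted(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, b, c in cells:
        counts[idx[a], idx[b]] += c
    return PairedContingency(classes=labels, counts=counts)


def load_validation_table(name: str) -> PairedContingency:
    """Load one of the packaged cohort tables by name (rows = manual
    rater A, columns = automated rater B)."""
    if name not in VALIDATION_TABLES:
        raise ValidationError(
            f"unknown table {name!r}; choose from {VALIDATION_TABLES}"
        )
    ref = resources.files("gsirads.data.contingency") / f"{name}.csv"
    with resources.as_file(ref) as path:
        return load_contingency_csv(path)
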