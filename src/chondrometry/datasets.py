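"""Bundled example data.

A small demonstration table of per-specimen condylar cartilage thickness
statistics (mean and SD in mm over each subregion) for three cadaveric
femurs, measured with the two-scan fiducial-registered pipeline this package
implements.  Useful for exercising :func:`chondrometry.summarize_study`
without any mesh inputs.
"""

from __future__ import annotations

import pandas as pd

# (specimen, condyle, flexion_deg, mean_mm, sd_mm)
_EXAMPLE_ROWS = [
    ("Specimen 1", "medial", 0, 2.0, 0.4),
    ("Specimen 1", "lateral", 0, 2.0, 0.3),
    ("Specimen 1", "medial", 90, 1.9, 0.3),
    ("Specimen 1", "lateral", 90, 2.0, 0.1),
    ("Specimen 2", "medial", 0, 2.2, 0.3),
    ("Specimen 2", "lateral", 0, 1.5, 0.3),
    ("Specimen 2", "medial", 90, 1.6, 0.1),
    ("Specimen 2", "lateral", 90, 1.9, 0.1),
    ("Specimen 3", "medial", 0, 1.5, 0.4),
    ("Specimen 3", "lateral", 0, 2.8, 0.2),
    ("Specimen 3", "medial", 90, 1.2, 0.3),
    ("Specimen 3", "lateral", 90, 2.3, 0.3),
]


def load_example_study() -> pd.DataFrame:
    """Long-form table of example per-specimen subregion thickness stats."""
    return pd.DataFrame(
        _EXAMPLE_ROWS, columns=["specimen", "condyle", "flexion_deg", "mean_mm", "sd_mm"]
    )
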