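"""Expression-matrix container.

Expression data are kept in the orientation used by series-matrix style
files: probes (or genes) as rows, samples as columns.  A ``scale`` flag
records whether values are already log2-transformed; scoring applies
``log2(x + 1)`` itself when the flag says ``linear``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("log2", "linear")


@dataclass
class ExpressionMatrix:
    """Probe x sample numeric matrix with scale metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe/gene identifier, columns by sample identifier.
    scale : str
        ``"log2"`` (default) or ``"linear"``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix must be numeric")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], scale=self.scale)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(probe_ids)], scale=self.scale)
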