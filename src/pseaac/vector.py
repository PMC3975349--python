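"""The DescriptorVector container emitted by every mode."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DescriptorVector:
    """Named, ordered numeric features emitted by one mode for one protein.

    Parameters
    ----------
    mode_name:
        Registry name of the mode that produced the vector.
    feature_names:
        Ordered feature labels; deterministic for a given mode + parameters.
    values:
        Equal-length float array; all entries finite.
    """

    mode_name: str
    feature_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if len(self.feature_names) != vals.shape[0]:
            raise ValueError(
                f"{self.mode_name}: {len(self.feature_names)} names vs "
                f"{vals.shape[0]} values"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.mode_name}: non-finite descriptor values")

    def __len__(self) -> int:
        return self.values.shape[0]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.values.tolist()))
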