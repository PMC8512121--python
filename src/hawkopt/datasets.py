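"""Bundled reference data.

Two small plain-text tables ship with the package:

* ``cec2019_published_means.csv`` — mean final objective values of eleven
  metaheuristics (including basic HHO and the enhanced variant) over the ten
  CEC2019 functions, 50 runs of 25,000 evaluations each, transcribed from
  the published comparison these statistics were designed around.  It is the
  worked input for the Friedman/Iman-Davenport/Holm battery.
* ``mri_confusion_ehho.csv`` / ``mri_confusion_mfa.csv`` — one-vs-rest
  confusion counts (and the originally reported metric columns) of the two
  best evolved CNN classifiers on the two MRI brain-tumor datasets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ranking import ResultTable

__all__ = ["load_published_means", "load_confusion_table"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("hawkopt.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, **kwargs)


def load_published_means() -> ResultTable:
    """The 10-function x 11-algorithm published mean-results table."""
    mean = _read("cec2019_published_means.csv", index_col=0)
    return ResultTable(mean=mean)


def load_confusion_table(model: str = "ehho") -> pd.DataFrame:
    """Confusion counts + reported metrics for an evolved classifier.

    ``model`` is ``"ehho"`` (the enhanced-HHO-designed CNN) or ``"mfa"``
    (the modified-firefly-designed CNN used as the runner-up comparison).
    """
    if model not in ("ehho", "mfa"):
        raise ValueError("model must be 'ehho' or 'mfa'")
    return _read(f"mri_confusion_{model}.csv")
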