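"""Replicate reproducibility by Pearson correlation (the 1-PCC test).

For each biological sample, all pairwise Pearson correlation coefficients
between its technical-replicate spectra are computed across the wavenumber
axis; the variability score is 1 minus their mean.  Identical replicates
give 0; anticorrelated ones give 2.  Samples measured under conditions that
degrade reproducibility (e.g. laser heating mitigated by reduced power)
surface at the top of the ranking.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DesignError
from .spectra_io import SpectraSet

_BIO_KEYS = ["strain", "pi_level", "ca_level", "bio_rep"]


def replicate_pcc(sset: SpectraSet) -> pd.DataFrame:
    """Per-sample pairwise replicate PCCs and the 1-PCC variability score.

    Expects preprocessed non-derivative data with ≥ 2 technical replicates
    per biological sample.  Pairs involving a zero-variance spectrum (PCC
    undefined) are excluded from the mean with a warning and counted in
    ``n_undefined_pairs``.  The result is sorted by descending variability.
    """
    meta = sset.meta
    groups = meta.groupby(_BIO_KEYS, sort=True).indices
    rows = []
    for key, idx in groups.items():
        idx = np.sort(np.asarray(idx))
        if idx.size < 2:
            raise DesignError(
                f"sample {key} has {idx.size} technical replicate(s); need ≥ 2"
            )
        specs = sset.matrix[idx]
        sd = specs.std(axis=1)
        pccs, undefined = [], 0
        for i in range(idx.size):
            for j in range(i + 1, idx.size):
                if sd[i] == 0 or sd[j] == 0:
                    undefined += 1
                    continue
                pccs.append(float(np.corrcoef(specs[i], specs[j])[0, 1]))
        strain, pi, ca, rep = key
        sid = f"{strain}-Pi{pi:g}-Ca{int(ca)}-B{int(rep)}"
        if undefined:
            warnings.warn(
                f"sample {sid}: {undefined} replicate pair(s) with zero-variance "
                "spectrum excluded from the PCC mean",
                stacklevel=2,
            )
        mean_pcc = float(np.mean(pccs)) if pccs else np.nan
        rows.append(
            {
                "sample_id": sid,
                "strain": strain,
                "pi_level": float(pi),
                "ca_level": int(ca),
                "bio_rep": int(rep),
                "laser_power_mw": float(meta["laser_power_mw"].iloc[idx[0]]),
                "n_pairs": len(pccs),
                "n_undefined_pairs": undefined,
                "mean_pcc": mean_pcc,
                "variability": 1.0 - mean_pcc if pccs else np.nan,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "variability", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)
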