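"""Across-patient correlations between rim CBF and the MEG/BOLD measures.

Runs any missing upstream stages, then correlates each patient's
rim-mean CBF with the rim-mean MEG measures (and BOLD variability) —
the across-subject coupling of hypoperfusion with spectral slowing:
negative r for delta and long-scale MSE, positive for alpha and beta,
and no systematic relationship in the mirror ROI or for BOLD measures.
"""

import importlib
from pathlib import Path

import pandas as pd

from restdyn.pipeline import run_pipeline

cfgmod = importlib.import_module("00_config")


def main() -> None:
    cfg = cfgmod.main_config(cfgmod.parse_seed())
    out = Path(cfg.out_dir)
    stages = ["correlate"]
    # reuse cached stage outputs where they exist
    if not (out / "meg_roi_measures.tsv").exists():
        stages = ["rois", "meg", "bold", "cbf"] + stages
    elif not (out / "cbf_roi.tsv").exists():
        stages = ["rois", "cbf"] + stages
    cfg.stages = tuple(stages)
    run_pipeline(cfg)

    df = pd.read_csv(out / "cbf_correlations.tsv", sep="\t")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
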