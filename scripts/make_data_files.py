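"""Regenerate the packaged CSV data files (deterministic)."""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

DATA = Path(__file__).resolve().parents[1] / "src" / "ccvmotor" / "data"
DATA.mkdir(exist_ok=True)

# ---- parametric tract geometry (synthetic stand-in for MRI-derived modes)
L, n = 17.5, 101
x = np.linspace(0.0, L, n)
geo = pd.DataFrame(
    {
        "x": x,
        "omega": 1.5 + 0.4 * np.sin(np.pi * x / L),
        "phi1": np.cos(np.pi * x / L),
        "phi2": np.cos(2 * np.pi * x / L),
    }
)
header = (
    "# Synthetic parametric vocal-tract geometry (not anatomical data).\n"
    "# Omega(x) = 1.5 + 0.4 sin(pi x / L) cm; phi1 = cos(pi x/L); phi2 = cos(2 pi x/L);\n"
    "# L = 17.5 cm, 101 points. Stand-in for MRI-derived orthogonal decompositions,\n"
    "# which are not redistributable. Swappable via ccvmotor.tract_model.load_geometry.\n"
)
with open(DATA / "default_tract.csv", "w") as fh:
    fh.write(header)
    geo.to_csv(fh, index=False, float_format="%.10g")

# ---- per-CCV timing calibration (from the measured subgroup statistics)
voiced = ["bda", "bga", "dba", "dga", "gba", "gda"]
low_group = ["bda", "bga", "dga"]       # canonical place ordering
high_group = ["dba", "gba", "gda"]      # interchanged consonants
devoiced = ["bpa", "bta", "bca", "dpa", "dta", "dca", "gpa", "gta", "gca"]
rows = []
for ccv in low_group:
    rows.append((ccv, 0.373))
for ccv in high_group:
    rows.append((ccv, 0.390))
for ccv in devoiced:
    rows.append((ccv, 0.413))
cal = pd.DataFrame(rows, columns=["ccv", "tau_norm_mean"])
cal["tau_norm_sd"] = 0.065
cal["T_mean"] = 0.490
cal["T_sd"] = 0.050
with open(DATA / "ccv_calibration.csv", "w") as fh:
    fh.write(
        "# Timing calibration for the 15 plosive-plosive analysis CCVs.\n"
        "# tau_norm_mean reproduces the measured subgroup means of the normalized\n"
        "# consonantal transition tau' (0.373 / 0.390 / 0.413); per-CCV means are\n"
        "# not published, so subgroup means are assigned uniformly within subgroup.\n"
        "# tau_norm_sd back-solved from the printed group standard errors.\n"
    )
    cal.to_csv(fh, index=False)

# ---- synthetic intra-word frequency table (corpus mining out of scope)
PLOSIVES = ("b", "d", "g", "p", "t", "c")
FRICATIVES = ("s", "f", "j")
consonants = list(PLOSIVES) + list(FRICATIVES)
rng = np.random.default_rng(20260929)
rows = []
# hand-set plosive-plosive values: homogeneously low except bta (high)
# and a couple of t-clusters in the medium band
pp_special = {"bta": 60.0, "dta": 15.0, "gta": 12.0}
for c1 in consonants:
    for c2 in consonants:
        if c1 == c2:
            continue
        ccv = f"{c1}{c2}a"
        pp = c1 in PLOSIVES and c2 in PLOSIVES
        if pp:
            f = pp_special.get(ccv, round(float(rng.uniform(0.2, 6.0)), 1))
        else:
            # fricative-containing clusters: higher and far more variable
            f = round(float(10 ** rng.uniform(0.3, 3.5)), 1)
        rows.append((ccv, f))
freq = pd.DataFrame(rows, columns=["ccv", "f"])
with open(DATA / "ccv_frequency_synthetic.csv", "w") as fh:
    fh.write(
        "# SYNTHETIC intra-word frequency table (appearances per million words).\n"
        "# Plausible stand-in values, NOT corpus-mined: plosive-plosive clusters\n"
        "# homogeneously low (bta high, dta/gta medium), fricative-containing\n"
        "# clusters higher and more variable. Deterministic (seed 20260929).\n"
    )
    freq.to_csv(fh, index=False)

print("wrote", sorted(p.name for p in DATA.glob("*.csv")))
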