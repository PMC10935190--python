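"""Calibrate an ear-moisture PLS model, including the pretreatment survey.

Averages replicate scans per (ear, instrument), converts reflectance to
absorbance, surveys a few candidate pretreatments with Venetian-blinds
cross-validation, and fits the final model with automatic latent-variable
selection.
"""

from dataclasses import replace

import silagescan as ss
from silagescan.spectra import from_frame

# a scaled-down season keeps the survey quick; the full design uses 610 ears
season = replace(ss.season_preset(2021), n_plants=120)
spectra_df, ref_df = ss.simulate_campaign([season], ss.default_profiles(),
                                          seed=7)
ref = ref_df.set_index("ear_id")

raw = from_frame(spectra_df)
averaged = ss.average_replicates(raw, by=("ear_id", "instrument_id"))
absorbance = ss.to_absorbance(averaged)
y = ref.loc[absorbance.keys["ear_id"], "ear_moisture_wb"].to_numpy()

candidates = [
    ss.PreprocessSpec("none"),
    ss.PreprocessSpec("msc"),
    ss.PreprocessSpec.from_shorthand("D-2,2,11"),
    ss.PreprocessSpec.from_shorthand("D-1,2,11"),
]
survey = ss.optimize_preprocessing(absorbance.values, y,
                                   candidates=candidates, max_lv=10)
print("pretreatment survey (ranked by RMSECV; lower is better):")
print(survey[["pretreatment", "n_lv", "rmsec", "rmsecv", "r2cv"]]
      .round(3).to_string(index=False))

best = survey.iloc[0]["spec"]
model = ss.calibrate(absorbance.values, y, spec=best, max_lv=10,
                     grid_fingerprint=absorbance.grid_fingerprint())
at = model.cv_table.iloc[model.n_lv - 1]
print(f"\nfinal model: {best.shorthand()} with {model.n_lv} latent variables")
print(f"SEC {at['sec']:.2f}  R2C {at['r2c']:.3f}  "
      f"SECV {at['secv']:.2f}  R2CV {at['r2cv']:.3f}")
# SEC/SECV are bias-corrected calibration / cross-validation errors in
# moisture percentage points; close agreement means the model is not overfit.
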