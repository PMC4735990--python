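# Default classifier thresholds.
# Calibrated once on the synthetic archetype distributions as the
# midpoint between group means (scripts/calibrate_thresholds.py,
# 200 cases/group, effect 1.0, calibration seed 12345); overridable
# per run.
thresholds:
  tau_hydrophobic_peak: 0.893
  tau_charge: 0.996
  tau_hydrophilic: 1.655
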