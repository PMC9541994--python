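{
  "wages": {
    "bedside-physician": {"central": 1.72, "low": 1.41, "high": 1.99},
    "radiologist": {"central": 1.89, "low": 1.66, "high": 2.06},
    "registered-nurse": {"central": 0.64, "low": 0.52, "high": 0.79},
    "radiology-technician": {"central": 0.51, "low": 0.42, "high": 0.63}
  },
  "times": {
    "mdTimeA": {"central": 3.0, "low": 2.0, "high": 4.0},
    "mdTimeB": {"central": 5.6, "low": 3.1, "high": 8.1},
    "radiologistRead": {"central": 3.0, "low": 2.0, "high": 4.0},
    "rnTimeB": {"central": 5.6, "low": 3.1, "high": 8.1},
    "techTimeA": {"central": 15.0, "low": 10.0, "high": 20.0}
  },
  "probabilities": {
    "pMalposition": {"central": 0.068, "low": 0.026, "high": 0.176},
    "pPneumothorax": {"central": 0.011, "low": 0.011, "high": 0.032},
    "source": "smit2018"
  },
  "population": {
    "hospitalCvcTotal": 3069,
    "hospitalCxrConfirmed": 2045,
    "nationalCvcTotal": 5000000,
    "supradiaphragmaticFraction": 0.66,
    "nationalEligible": 3300000
  }
}
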