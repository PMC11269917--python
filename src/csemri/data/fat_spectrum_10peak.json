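{
  "name": "subcutaneous_triglyceride_10peak",
  "description": "10-peak subcutaneous adipose triglyceride proton spectrum. Positions are the standard triglyceride resonances; relative amplitudes follow the triglyceride proton-count model with chain length 17.4, 2.8 double bonds and 0.7 methylene-interrupted double bonds per molecule. Water reference at 4.70 ppm. Amplitudes are proton counts; the loader normalizes them to sum to 1.",
  "water_ppm": 4.70,
  "peaks": [
    {"label": "olefinic CH=CH",      "ppm": 5.29, "protons": 5.6},
    {"label": "glycerol CH",         "ppm": 5.19, "protons": 1.0},
    {"label": "glycerol CH2 (a)",    "ppm": 4.30, "protons": 2.0},
    {"label": "glycerol CH2 (b)",    "ppm": 4.10, "protons": 2.0},
    {"label": "diallylic CH2",       "ppm": 2.75, "protons": 1.4},
    {"label": "alpha-carboxyl CH2",  "ppm": 2.24, "protons": 6.0},
    {"label": "alpha-olefinic CH2",  "ppm": 2.02, "protons": 8.4},
    {"label": "beta-carboxyl CH2",   "ppm": 1.60, "protons": 6.0},
    {"label": "methylene (CH2)n",    "ppm": 1.30, "protons": 59.4},
    {"label": "methyl CH3",          "ppm": 0.90, "protons": 9.0}
  ]
}
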