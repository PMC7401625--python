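# Claimed (in-house laboratory) canine reference intervals for the 21-analyte
# CBC + biochemistry panel, with display units and rounding decimals.
RBC:         {low: 5.10,  high: 7.80,   units: "10^12/L",  decimals: 2}
Hb:          {low: 12.5,  high: 19.4,   units: "g/dL",     decimals: 1}
HCT:         {low: 34.0,  high: 51.5,   units: "%",        decimals: 1}
MCV:         {low: 60.0,  high: 72.0,   units: "fL",       decimals: 1}
MCH:         {low: 22.1,  high: 26.5,   units: "pg",       decimals: 1}
MCHC:        {low: 34.5,  high: 38.3,   units: "g/dL",     decimals: 1}
RDW:         {low: 13.2,  high: 19.1,   units: "%",        decimals: 1}
PLT:         {low: 115,   high: 423,    units: "10^3/uL",  decimals: 0}
WBC:         {low: 5.60,  high: 17.80,  units: "10^3/uL",  decimals: 2}
Neutrophils: {low: 3.20,  high: 13.40,  units: "10^3/uL",  decimals: 2}
Lymphocytes: {low: 1.20,  high: 5.50,   units: "10^3/uL",  decimals: 2}
Monocytes:   {low: 0.50,  high: 1.80,   units: "10^3/uL",  decimals: 2}
Eosinophils: {low: 0.15,  high: 2.90,   units: "10^3/uL",  decimals: 2}
Basophils:   {low: 0.00,  high: 0.05,   units: "10^3/uL",  decimals: 2}
Albumin:     {low: 2.90,  high: 3.50,   units: "g/dL",     decimals: 2}
TP:          {low: 6.00,  high: 8.50,   units: "g/dL",     decimals: 2}
Urea:        {low: 20.0,  high: 40.0,   units: "mg/dL",    decimals: 1}
Creatinine:  {low: 0.5,   high: 1.6,    units: "mg/dL",    decimals: 2}
AST:         {low: 9.0,   high: 40.0,   units: "IU/L",     decimals: 1}
ALT:         {low: 7.0,   high: 40.0,   units: "IU/L",     decimals: 1}
ALP:         {low: 10.0,  high: 100.0,  units: "IU/L",     decimals: 1}
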