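sample_id,published_mg_per_100g,replicate_index,analytic_prediction,logical_prediction
Suntory A,40,1,47.46,47.70
Suntory A,40,2,47.30,49.79
Suntory A,40,3,38.97,44.75
Suntory B,40,1,38.56,46.07
Suntory B,40,2,38.48,45.05
Suntory B,40,3,38.61,45.89
Coca-Cola A,60,1,62.48,62.94
Coca-Cola A,60,2,56.87,54.74
Coca-Cola A,60,3,62.72,66.57
UCC A,60,1,50.44,52.85
UCC A,60,2,57.14,55.36
UCC A,60,3,49.19,51.11
Asahi A,62,1,59.03,54.43
Asahi A,62,2,60.89,60.19
Asahi A,62,3,63.70,65.10
KIRIN A,70,1,70.00,76.72
KIRIN A,70,2,64.14,70.80
KIRIN A,70,3,61.33,63.04
Asahi B,70,1,76.34,74.76
Asahi B,70,2,70.78,66.59
Asahi B,70,3,70.5,65.69
KIRIN B,78,1,75.05,64.24
KIRIN B,78,2,75.69,70.79
KIRIN B,78,3,76.18,71.89
Asahi C,80,1,80.78,85.60
Asahi C,80,2,83.02,80.42
Asahi C,80,3,82.65,77.42
Suntory C,82,1,78.27,82.47
Suntory C,82,2,81.90,91.80
Suntory C,82,3,78.51,77.19
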