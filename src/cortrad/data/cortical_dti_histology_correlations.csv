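region,metric,histology,r,p,p_fdr_printed
BA9,AngleR,minicolumn_width,0.912,0.001,0.030
BA41,AngleR,minicolumn_width,0.817,0.013,0.1671
V1,AngleR,minicolumn_width,-0.578,0.103,0.4414
BA9,AngleR,neuropil_spacing,0.773,0.024,0.24
BA41,AngleR,neuropil_spacing,0.833,0.01,0.15
V1,AngleR,neuropil_spacing,-0.398,0.288,0.7482
BA9,AngleR,core_width,0.879,0.002,0.045
BA41,AngleR,core_width,0.849,0.007,0.126
V1,AngleR,core_width,0.387,0.304,0.76
BA9,AngleR,microsegment_number,-0.654,0.056,0.336
BA41,AngleR,microsegment_number,-0.786,0.021,0.2362
V1,AngleR,microsegment_number,0.548,0.127,0.4762
BA9,AngleR,bundle_spacing,0.937,0.000,0
BA41,AngleR,bundle_spacing,0.069,0.859,0.9677
V1,AngleR,bundle_spacing,-0.603,0.086,0.4168
BA9,AngleR,bundle_width,0.192,0.621,0.9267
BA41,AngleR,bundle_width,0.179,0.645,0.9267
V1,AngleR,bundle_width,-0.691,0.054,0.336
BA9,PerpPD,minicolumn_width,0.949,0.949,0.9677
BA41,PerpPD,minicolumn_width,-0.664,0.073,0.3864
V1,PerpPD,minicolumn_width,0.131,0.737,0.9475
BA9,PerpPD,neuropil_spacing,0.778,0.778,0.9677
BA41,PerpPD,neuropil_spacing,-0.469,0.241,0.7054
V1,PerpPD,neuropil_spacing,-0.138,0.723,0.9430
BA9,PerpPD,core_width,0.591,0.591,0.9267
BA41,PerpPD,core_width,-0.557,0.152,0.5472
V1,PerpPD,core_width,0.038,0.923,0.9677
BA9,PerpPD,microsegment_number,0.515,0.515,0.9069
BA41,PerpPD,microsegment_number,0.696,0.051,0.336
V1,PerpPD,microsegment_number,-0.102,0.794,0.9677
BA9,PerpPD,bundle_spacing,0.659,0.659,0.9267
BA41,PerpPD,bundle_spacing,-0.068,0.863,0.9677
V1,PerpPD,bundle_spacing,0.297,0.438,0.8628
BA9,PerpPD,bundle_width,0.878,0.878,0.9677
BA41,PerpPD,bundle_width,0.347,0.361,0.8517
V1,PerpPD,bundle_width,0.548,0.126,0.4762
BA9,ParlPD,minicolumn_width,0.142,0.716,0.9430
BA41,ParlPD,minicolumn_width,-0.357,0.386,0.8517
V1,ParlPD,minicolumn_width,0.415,0.266,0.7481
BA9,ParlPD,neuropil_spacing,-0.190,0.625,0.9267
BA41,ParlPD,neuropil_spacing,-0.296,0.477,0.8797
V1,ParlPD,neuropil_spacing,0.139,0.721,0.9430
BA9,ParlPD,core_width,0.184,0.635,0.9267
BA41,ParlPD,core_width,-0.252,0.547,0.9116
V1,ParlPD,core_width,0.233,0.545,0.9116
BA9,ParlPD,microsegment_number,-0.071,0.856,0.9677
BA41,ParlPD,microsegment_number,0.355,0.388,0.8517
V1,ParlPD,microsegment_number,-0.377,0.317,0.7710
BA9,ParlPD,bundle_spacing,0.139,0.721,0.9430
BA41,ParlPD,bundle_spacing,0.307,0.422,0.8628
V1,ParlPD,bundle_spacing,0.664,0.051,0.336
BA9,ParlPD,bundle_width,-0.089,0.820,0.9677
BA41,ParlPD,bundle_width,-0.341,0.369,0.8515
V1,ParlPD,bundle_width,0.911,0.001,0.030
BA9,FA,minicolumn_width,0.180,0.643,0.9267
BA41,FA,minicolumn_width,0.639,0.088,0.4168
V1,FA,minicolumn_width,-0.397,0.291,0.7482
BA9,FA,neuropil_spacing,0.295,0.441,0.8628
BA41,FA,neuropil_spacing,0.707,0.050,0.336
V1,FA,neuropil_spacing,-0.272,0.479,0.8798
BA9,FA,core_width,0.034,0.930,0.9677
BA41,FA,core_width,0.675,0.067,0.3768
V1,FA,core_width,-0.398,0.289,0.7482
BA9,FA,microsegment_number,-0.434,0.243,0.7054
BA41,FA,microsegment_number,-0.588,0.125,0.4762
V1,FA,microsegment_number,0.436,0.240,0.7054
BA9,FA,bundle_spacing,-0.048,0.903,0.9677
BA41,FA,bundle_spacing,0.246,0.524,0.9069
V1,FA,bundle_spacing,-0.484,0.187,0.63
BA9,FA,bundle_width,0.090,0.817,0.9677
BA41,FA,bundle_width,0.482,0.189,0.63
V1,FA,bundle_width,-0.287,0.455,0.8712
BA9,MD,minicolumn_width,-0.162,0.678,0.9387
BA41,MD,minicolumn_width,-0.032,0.941,0.9677
V1,MD,minicolumn_width,0.310,0.417,0.8628
BA9,MD,neuropil_spacing,-0.223,0.563,0.9212
BA41,MD,neuropil_spacing,-0.284,0.496,0.8928
V1,MD,neuropil_spacing,0.057,0.884,0.9677
BA9,MD,core_width,0.029,0.942,0.9677
BA41,MD,core_width,0.051,0.905,0.9677
V1,MD,core_width,0.173,0.657,0.9267
BA9,MD,microsegment_number,0.443,0.233,0.7489
BA41,MD,microsegment_number,0.009,0.984,0.984
V1,MD,microsegment_number,-0.319,0.402,0.8614
BA9,MD,bundle_spacing,0.021,0.957,0.9677
BA41,MD,bundle_spacing,0.204,0.598,0.9267
V1,MD,bundle_spacing,0.592,0.093,0.4185
BA9,MD,bundle_width,0.045,0.909,0.9677
BA41,MD,bundle_width,-0.049,0.901,0.9677
V1,MD,bundle_width,0.696,0.051,0.336
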