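# name: paper-cohort
# seed: 20230
# shape: 64 64 204
# grid_nm: 400.0 2.941
# lambda_nm: 654.0
patient_id,brightness_b,brightness_a,contrast_b,contrast_a,homogeneity_b,homogeneity_a,refl654_b,refl654_a
P01,146.307648,161.807648,8.238795,7.238795,0.307988,0.407988,854.000000,932.000000
P02,163.923114,159.923114,6.741516,6.141516,0.365316,0.485316,793.000000,869.000000
P03,147.801938,169.801938,6.449753,4.549753,0.478216,0.698216,893.000000,961.000000
P04,169.444430,177.444430,6.112348,6.262348,0.486367,0.646367,830.000000,914.000000
P05,121.005677,158.085677,6.024105,4.724105,0.492665,0.632665,966.000000,1012.000000
P06,126.322094,138.322094,5.892537,5.192537,0.508843,0.558843,846.000000,926.000000
P07,197.658941,195.658941,5.851132,4.951132,0.549550,0.739550,760.000000,841.000000
P08,123.429116,149.429116,5.841362,6.141362,0.594034,0.554034,912.000000,983.000000
P09,118.081352,133.581352,5.829646,5.329646,0.643164,0.633164,854.000000,932.000000
P10,143.580772,173.580772,4.720296,4.370296,0.664748,0.644748,938.000000,998.000000
P11,132.374665,126.374665,4.514194,3.714194,0.736532,0.816532,815.000000,890.000000
P12,130.030251,148.030251,4.104318,3.904318,0.892576,0.862576,871.000000,947.000000
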