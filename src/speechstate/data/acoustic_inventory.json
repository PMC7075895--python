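{
 "version": "1",
 "n_features": 88,
 "features": [
  "Pitch_a",
  "Pitch_b",
  "Pitch_c",
  "Pitch_d",
  "Pitch_e",
  "Pitch_g",
  "Jitter_h",
  "Jitter_ppq5",
  "Shimmer_h",
  "Shimmer_apq5",
  "VoiceBreaks_n",
  "VoiceBreaks_degree",
  "HNR",
  "NHR",
  "MeanAutocorr",
  "Spectral_maxdB",
  "Spectral_maxfreq",
  "Spectral_energy",
  "Spectral_slope",
  "MFCC #1_a",
  "MFCC #1_b",
  "MFCC #2_a",
  "MFCC #2_b",
  "MFCC #3_a",
  "MFCC #3_b",
  "MFCC #4_a",
  "MFCC #4_b",
  "MFCC #5_a",
  "MFCC #5_b",
  "MFCC #6_a",
  "MFCC #6_b",
  "MFCC #7_a",
  "MFCC #7_b",
  "MFCC #8_a",
  "MFCC #8_b",
  "MFCC #9_a",
  "MFCC #9_b",
  "MFCC #10_a",
  "MFCC #10_b",
  "MFCC #11_a",
  "MFCC #11_b",
  "MFCC #12_a",
  "MFCC #12_b",
  "MFCC #13_a",
  "MFCC #13_b",
  "MFCC #14_a",
  "MFCC #14_b",
  "MFCC #15_a",
  "MFCC #15_b",
  "MFCC #16_a",
  "MFCC #16_b",
  "F1_a",
  "F1_b",
  "F1_c",
  "F1_d",
  "F1_e",
  "F1_g",
  "F2_a",
  "F2_b",
  "F2_c",
  "F2_d",
  "F2_e",
  "F2_g",
  "F3_a",
  "F3_b",
  "F3_c",
  "F3_d",
  "F3_e",
  "F3_g",
  "VowelSpace_total",
  "VowelSpace_aiu",
  "Angle",
  "PauseDist_a",
  "PauseDist_b",
  "PauseDist_c",
  "PauseDist_d",
  "PauseDist_e",
  "PauseDist_g",
  "PauseDist_max",
  "UttDist_a",
  "UttDist_b",
  "UttDist_e",
  "UttDist_g",
  "PauseCount",
  "Unvoiced_i",
  "SpeechRate",
  "ArticRate",
  "PhonationRatio"
 ]
}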