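api,label_claim_mg,batch_id,av,powder_loss_pct,sd_rel_mass_pct,sd_rel_content_pct,mean_content_mg,sd_rel_content_mass_pct
baclofen,1,m35-1mg-1,5.65,1.98,2.02,2.33,0.97,1.20
baclofen,1,m35-1mg-2,4.78,2.40,1.88,2.37,1.01,1.41
baclofen,1,m35-1mg-3,4.88,2.03,1.78,2.47,0.98,1.51
baclofen,1,la-1mg-1,5.03,2.37,1.83,2.48,0.98,1.72
baclofen,1,la-1mg-2,4.18,1.63,1.50,2.10,1.00,1.31
baclofen,1,la-1mg-3,6.70,2.22,1.19,2.04,0.96,1.31
baclofen,1,mcc-1mg-1,4.02,3.75,1.35,1.98,1.01,1.66
baclofen,1,mcc-1mg-2,4.32,3.89,0.79,2.18,0.99,2.16
baclofen,1,mcc-1mg-3,6.56,7.27,1.43,2.17,0.96,2.24
baclofen,2.5,m35-2.5mg-1,3.08,4.22,1.64,1.56,2.46,0.552
baclofen,2.5,m35-2.5mg-2,6.01,3.10,3.07,2.56,2.56,0.791
baclofen,2.5,m35-2.5mg-3,4.92,2.53,3.02,2.46,2.51,0.962
baclofen,2.5,la-2.5mg-1,5.15,1.95,2.13,2.57,2.50,1.15
baclofen,2.5,la-2.5mg-2,3.86,2.17,1.54,1.50,2.56,1.62
baclofen,2.5,la-2.5mg-3,2.66,1.69,1.41,1.30,2.54,0.947
baclofen,2.5,mcc-2.5mg-1,16.07,1.31,1.43,6.36,2.61,6.44
baclofen,2.5,mcc-2.5mg-2,5.54,4.67,1.36,2.50,2.55,2.13
baclofen,2.5,mcc-2.5mg-3,7.42,1.93,1.24,2.03,2.62,1.78
baclofen,4,m35-4mg-1,6.04,6.01,2.93,1.98,3.85,1.80
baclofen,4,m35-4mg-2,3.50,4.72,0.79,1.63,3.93,0.891
baclofen,4,m35-4mg-3,5.23,4.77,1.87,1.85,3.87,1.59
baclofen,4,la-4mg-1,13.16,3.16,1.81,4.26,3.73,3.30
baclofen,4,la-4mg-2,3.19,3.61,1.66,1.52,4.06,0.925
baclofen,4,la-4mg-3,4.22,7.07,1.69,1.81,3.91,1.41
baclofen,4,mcc-4mg-1,4.39,5.48,1.96,2.15,4.06,1.04
baclofen,4,mcc-4mg-2,4.12,5.72,2.05,1.58,4.10,0.675
baclofen,4,mcc-4mg-3,3.61,5.80,1.64,1.41,4.09,0.841
spironolactone,0.5,m35-0.5mg-1,8.83,6.72,1.40,2.17,0.469,1.40
spironolactone,0.5,m35-0.5mg-2,11.29,10.67,2.19,2.31,0.457,1.67
spironolactone,0.5,m35-0.5mg-3,17.00,10.84,1.98,2.28,0.427,1.38
spironolactone,0.5,la-0.5mg-1,5.81,3.87,2.38,2.91,0.485,1.71
spironolactone,0.5,la-0.5mg-2,3.35,2.77,1.82,1.69,0.492,1.02
spironolactone,0.5,la-0.5mg-3,4.37,3.26,2.12,2.25,0.483,1.03
spironolactone,0.5,mcc-0.5mg-1,7.51,4.54,2.17,2.30,0.455,1.88
spironolactone,0.5,mcc-0.5mg-2,10.40,2.50,1.27,3.12,0.448,3.05
spironolactone,0.5,mcc-0.5mg-3,5.87,4.14,1.85,2.99,0.475,2.32
spironolactone,2,m35-2mg-1,8.44,3.16,2.47,2.62,2.09,0.748
spironolactone,2,m35-2mg-2,4.24,4.66,2.39,2.12,2.00,0.704
spironolactone,2,m35-2mg-3,4.73,4.25,1.89,1.83,1.95,1.53
spironolactone,2,la-2mg-1,7.95,1.42,2.16,1.63,2.12,2.07
spironolactone,2,la-2mg-2,3.87,2.41,1.72,1.51,2.05,1.05
spironolactone,2,la-2mg-3,8.48,2.21,1.69,1.84,2.10,0.717
spironolactone,2,mcc-2mg-1,5.36,2.69,1.40,2.62,2.03,0.760
spironolactone,2,mcc-2mg-2,4.31,2.60,1.11,1.63,2.05,1.24
spironolactone,2,mcc-2mg-3,4.26,3.29,1.75,1.37,2.06,1.37
spironolactone,4,m35-4mg-1,4.54,4.46,1.89,2.27,4.06,1.98
spironolactone,4,m35-4mg-2,10.59,2.44,3.90,4.06,4.16,0.821
spironolactone,4,m35-4mg-3,6.18,3.03,2.83,2.26,4.13,0.611
spironolactone,4,la-4mg-1,13.61,2.20,1.65,3.33,4.34,1.75
spironolactone,4,la-4mg-2,5.94,2.29,1.74,2.74,4.08,1.71
spironolactone,4,la-4mg-3,7.57,1.55,2.30,2.56,4.16,1.07
spironolactone,4,mcc-4mg-1,7.87,3.14,0.92,2.83,4.15,2.61
spironolactone,4,mcc-4mg-2,2.67,3.74,0.74,1.33,4.05,1.23
spironolactone,4,mcc-4mg-3,4.54,4.46,1.89,2.27,4.06,1.77
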