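CHN1
CLTC
DDX10
MECOM
CGCSYN0000
CGCSYN0001
CGCSYN0002
CGCSYN0003
CGCSYN0004
CGCSYN0005
CGCSYN0006
CGCSYN0007
CGCSYN0008
CGCSYN0009
CGCSYN0010
CGCSYN0011
CGCSYN0012
CGCSYN0013
CGCSYN0014
CGCSYN0015
CGCSYN0016
CGCSYN0017
CGCSYN0018
CGCSYN0019
CGCSYN0020
CGCSYN0021
CGCSYN0022
CGCSYN0023
CGCSYN0024
CGCSYN0025
CGCSYN0026
CGCSYN0027
CGCSYN0028
CGCSYN0029
CGCSYN0030
CGCSYN0031
CGCSYN0032
CGCSYN0033
CGCSYN0034
CGCSYN0035
CGCSYN0036
CGCSYN0037
CGCSYN0038
CGCSYN0039
CGCSYN0040
CGCSYN0041
CGCSYN0042
CGCSYN0043
CGCSYN0044
CGCSYN0045
CGCSYN0046
CGCSYN0047
CGCSYN0048
CGCSYN0049
CGCSYN0050
CGCSYN0051
CGCSYN0052
CGCSYN0053
CGCSYN0054
CGCSYN0055
CGCSYN0056
CGCSYN0057
CGCSYN0058
CGCSYN0059
CGCSYN0060
CGCSYN0061
CGCSYN0062
CGCSYN0063
CGCSYN0064
CGCSYN0065
CGCSYN0066
CGCSYN0067
CGCSYN0068
CGCSYN0069
CGCSYN0070
CGCSYN0071
CGCSYN0072
CGCSYN0073
CGCSYN0074
CGCSYN0075
CGCSYN0076
CGCSYN0077
CGCSYN0078
CGCSYN0079
CGCSYN0080
CGCSYN0081
CGCSYN0082
CGCSYN0083
CGCSYN0084
CGCSYN0085
CGCSYN0086
CGCSYN0087
CGCSYN0088
CGCSYN0089
CGCSYN0090
CGCSYN0091
CGCSYN0092
CGCSYN0093
CGCSYN0094
CGCSYN0095
CGCSYN0096
CGCSYN0097
CGCSYN0098
CGCSYN0099
CGCSYN0100
CGCSYN0101
CGCSYN0102
CGCSYN0103
CGCSYN0104
CGCSYN0105
CGCSYN0106
CGCSYN0107
CGCSYN0108
CGCSYN0109
CGCSYN0110
CGCSYN0111
CGCSYN0112
CGCSYN0113
CGCSYN0114
CGCSYN0115
CGCSYN0116
CGCSYN0117
CGCSYN0118
CGCSYN0119
CGCSYN0120
CGCSYN0121
CGCSYN0122
CGCSYN0123
CGCSYN0124
CGCSYN0125
CGCSYN0126
CGCSYN0127
CGCSYN0128
CGCSYN0129
CGCSYN0130
CGCSYN0131
CGCSYN0132
CGCSYN0133
CGCSYN0134
CGCSYN0135
CGCSYN0136
CGCSYN0137
CGCSYN0138
CGCSYN0139
CGCSYN0140
CGCSYN0141
CGCSYN0142
CGCSYN0143
CGCSYN0144
CGCSYN0145
CGCSYN0146
CGCSYN0147
CGCSYN0148
CGCSYN0149
CGCSYN0150
CGCSYN0151
CGCSYN0152
CGCSYN0153
CGCSYN0154
CGCSYN0155
CGCSYN0156
CGCSYN0157
CGCSYN0158
CGCSYN0159
CGCSYN0160
CGCSYN0161
CGCSYN0162
CGCSYN0163
CGCSYN0164
CGCSYN0165
CGCSYN0166
CGCSYN0167
CGCSYN0168
CGCSYN0169
CGCSYN0170
CGCSYN0171
CGCSYN0172
CGCSYN0173
CGCSYN0174
CGCSYN0175
CGCSYN0176
CGCSYN0177
CGCSYN0178
CGCSYN0179
CGCSYN0180
CGCSYN0181
CGCSYN0182
CGCSYN0183
CGCSYN0184
CGCSYN0185
CGCSYN0186
CGCSYN0187
CGCSYN0188
CGCSYN0189
CGCSYN0190
CGCSYN0191
CGCSYN0192
CGCSYN0193
CGCSYN0194
CGCSYN0195
CGCSYN0196
CGCSYN0197
CGCSYN0198
CGCSYN0199
CGCSYN0200
CGCSYN0201
CGCSYN0202
CGCSYN0203
CGCSYN0204
CGCSYN0205
CGCSYN0206
CGCSYN0207
CGCSYN0208
CGCSYN0209
CGCSYN0210
CGCSYN0211
CGCSYN0212
CGCSYN0213
CGCSYN0214
CGCSYN0215
CGCSYN0216
CGCSYN0217
CGCSYN0218
CGCSYN0219
CGCSYN0220
CGCSYN0221
CGCSYN0222
CGCSYN0223
CGCSYN0224
CGCSYN0225
CGCSYN0226
CGCSYN0227
CGCSYN0228
CGCSYN0229
CGCSYN0230
CGCSYN0231
CGCSYN0232
CGCSYN0233
CGCSYN0234
CGCSYN0235
CGCSYN0236
CGCSYN0237
CGCSYN0238
CGCSYN0239
CGCSYN0240
CGCSYN0241
CGCSYN0242
CGCSYN0243
CGCSYN0244
CGCSYN0245
CGCSYN0246
CGCSYN0247
CGCSYN0248
CGCSYN0249
CGCSYN0250
CGCSYN0251
CGCSYN0252
CGCSYN0253
CGCSYN0254
CGCSYN0255
CGCSYN0256
CGCSYN0257
CGCSYN0258
CGCSYN0259
CGCSYN0260
CGCSYN0261
CGCSYN0262
CGCSYN0263
CGCSYN0264
CGCSYN0265
CGCSYN0266
CGCSYN0267
CGCSYN0268
CGCSYN0269
CGCSYN0270
CGCSYN0271
CGCSYN0272
CGCSYN0273
CGCSYN0274
CGCSYN0275
CGCSYN0276
CGCSYN0277
CGCSYN0278
CGCSYN0279
CGCSYN0280
CGCSYN0281
CGCSYN0282
CGCSYN0283
CGCSYN0284
CGCSYN0285
CGCSYN0286
CGCSYN0287
CGCSYN0288
CGCSYN0289
CGCSYN0290
CGCSYN0291
CGCSYN0292
CGCSYN0293
CGCSYN0294
CGCSYN0295
CGCSYN0296
CGCSYN0297
CGCSYN0298
CGCSYN0299
CGCSYN0300
CGCSYN0301
CGCSYN0302
CGCSYN0303
CGCSYN0304
CGCSYN0305
CGCSYN0306
CGCSYN0307
CGCSYN0308
CGCSYN0309
CGCSYN0310
CGCSYN0311
CGCSYN0312
CGCSYN0313
CGCSYN0314
CGCSYN0315
CGCSYN0316
CGCSYN0317
CGCSYN0318
CGCSYN0319
CGCSYN0320
CGCSYN0321
CGCSYN0322
CGCSYN0323
CGCSYN0324
CGCSYN0325
CGCSYN0326
CGCSYN0327
CGCSYN0328
CGCSYN0329
CGCSYN0330
CGCSYN0331
CGCSYN0332
CGCSYN0333
CGCSYN0334
CGCSYN0335
CGCSYN0336
CGCSYN0337
CGCSYN0338
CGCSYN0339
CGCSYN0340
CGCSYN0341
CGCSYN0342
CGCSYN0343
CGCSYN0344
CGCSYN0345
CGCSYN0346
CGCSYN0347
CGCSYN0348
CGCSYN0349
CGCSYN0350
CGCSYN0351
CGCSYN0352
CGCSYN0353
CGCSYN0354
CGCSYN0355
CGCSYN0356
CGCSYN0357
CGCSYN0358
CGCSYN0359
CGCSYN0360
CGCSYN0361
CGCSYN0362
CGCSYN0363
CGCSYN0364
CGCSYN0365
CGCSYN0366
CGCSYN0367
CGCSYN0368
CGCSYN0369
CGCSYN0370
CGCSYN0371
CGCSYN0372
CGCSYN0373
CGCSYN0374
CGCSYN0375
CGCSYN0376
CGCSYN0377
CGCSYN0378
CGCSYN0379
CGCSYN0380
CGCSYN0381
CGCSYN0382
CGCSYN0383
CGCSYN0384
CGCSYN0385
CGCSYN0386
CGCSYN0387
CGCSYN0388
CGCSYN0389
CGCSYN0390
CGCSYN0391
CGCSYN0392
CGCSYN0393
CGCSYN0394
CGCSYN0395
CGCSYN0396
CGCSYN0397
CGCSYN0398
CGCSYN0399
CGCSYN0400
CGCSYN0401
CGCSYN0402
CGCSYN0403
CGCSYN0404
CGCSYN0405
CGCSYN0406
CGCSYN0407
CGCSYN0408
CGCSYN0409
CGCSYN0410
CGCSYN0411
CGCSYN0412
CGCSYN0413
CGCSYN0414
CGCSYN0415
CGCSYN0416
CGCSYN0417
CGCSYN0418
CGCSYN0419
CGCSYN0420
CGCSYN0421
CGCSYN0422
CGCSYN0423
CGCSYN0424
CGCSYN0425
CGCSYN0426
CGCSYN0427
CGCSYN0428
CGCSYN0429
CGCSYN0430
CGCSYN0431
CGCSYN0432
CGCSYN0433
CGCSYN0434
CGCSYN0435
CGCSYN0436
CGCSYN0437
CGCSYN0438
CGCSYN0439
CGCSYN0440
CGCSYN0441
CGCSYN0442
CGCSYN0443
CGCSYN0444
CGCSYN0445
CGCSYN0446
CGCSYN0447
CGCSYN0448
CGCSYN0449
CGCSYN0450
CGCSYN0451
CGCSYN0452
CGCSYN0453
CGCSYN0454
CGCSYN0455
CGCSYN0456
CGCSYN0457
CGCSYN0458
CGCSYN0459
CGCSYN0460
CGCSYN0461
CGCSYN0462
CGCSYN0463
CGCSYN0464
CGCSYN0465
CGCSYN0466
CGCSYN0467
CGCSYN0468
CGCSYN0469
CGCSYN0470
CGCSYN0471
CGCSYN0472
CGCSYN0473
CGCSYN0474
CGCSYN0475
CGCSYN0476
CGCSYN0477
CGCSYN0478
CGCSYN0479
CGCSYN0480
CGCSYN0481
CGCSYN0482
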