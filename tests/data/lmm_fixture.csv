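participant_id,x,y
P00,60.0,57.46243932121408
P00,80.0,75.20363810209965
P00,100.0,62.12770262668717
P00,120.0,84.45632301964037
P00,140.0,114.59658569497441
P00,160.0,125.99581931490377
P00,60.0,49.78991578810661
P00,80.0,57.26755166245171
P00,100.0,90.43203426185381
P00,120.0,105.25603744255302
P00,140.0,113.97848863891372
P00,160.0,140.43065730801993
P00,60.0,54.633020785669956
P00,80.0,57.20506630935513
P00,100.0,85.32556235405052
P00,120.0,87.88929207997356
P00,140.0,122.10268467637428
P00,160.0,128.65898612847707
P01,60.0,62.57535994553092
P01,80.0,66.08093356048683
P01,100.0,80.61923198192801
P01,120.0,98.65745652106102
P01,140.0,124.77816570386105
P01,160.0,140.38579631435258
P01,60.0,54.4772726747505
P01,80.0,71.93443841125368
P01,100.0,106.3189862122637
P01,120.0,98.11464186209717
P01,140.0,114.33264655761218
P01,160.0,128.59362838823301
P01,60.0,56.50974078454558
P01,80.0,78.91595130838377
P01,100.0,83.76303562701034
P01,120.0,93.77722725631804
P01,140.0,111.21026169141516
P01,160.0,143.2372835489588
P02,60.0,65.80878751640293
P02,80.0,96.95811489317785
P02,100.0,117.97597682713872
P02,120.0,141.16862177624233
P02,140.0,169.8686406616549
P02,160.0,185.56292544314059
P02,60.0,79.25302022000882
P02,80.0,95.31229235739957
P02,100.0,119.70031272263128
P02,120.0,145.2946180673376
P02,140.0,146.58279468361633
P02,160.0,180.13025779182075
P02,60.0,67.76015804636192
P02,80.0,88.24772318007723
P02,100.0,114.0576962234646
P02,120.0,153.93114892129617
P02,140.0,152.49604172524056
P02,160.0,193.00975350130858
P03,60.0,44.145952118294325
P03,80.0,67.04110466089395
P03,100.0,86.95160702528662
P03,120.0,106.43327345941422
P03,140.0,113.67301026498751
P03,160.0,131.1972029408831
P03,60.0,51.09818027981581
P03,80.0,59.26583809848502
P03,100.0,67.08247799397886
P03,120.0,87.16692896738016
P03,140.0,107.96573812745578
P03,160.0,140.7923283080664
P03,60.0,43.94267882794992
P03,80.0,68.08373488797885
P03,100.0,75.56681476399274
P03,120.0,100.08519801818211
P03,140.0,123.41616492714526
P03,160.0,132.72725547032638
P04,60.0,52.08055214200876
P04,80.0,69.24600790340958
P04,100.0,78.45728662323587
P04,120.0,112.63770412271549
P04,140.0,120.42625214856581
P04,160.0,142.59751297360333
P04,60.0,60.51855719671857
P04,80.0,77.5286986036923
P04,100.0,97.06953416885413
P04,120.0,106.78312446976544
P04,140.0,120.88729243015152
P04,160.0,141.67538967726247
P04,60.0,38.83774626807918
P04,80.0,58.59226211916199
P04,100.0,77.18868695558224
P04,120.0,97.79551103884485
P04,140.0,129.11801781782742
P04,160.0,133.41778123272584
P05,60.0,69.0027994305034
P05,80.0,105.1375080169328
P05,100.0,113.62308872330743
P05,120.0,146.10180313587415
P05,140.0,163.8528713565889
P05,160.0,195.15967433783337
P05,60.0,80.96852051569162
P05,80.0,80.48914810033844
P05,100.0,127.30350195886477
P05,120.0,150.53353473787325
P05,140.0,167.41159234872677
P05,160.0,184.08942655295445
P05,60.0,73.28673421825636
P05,80.0,92.4674252416239
P05,100.0,125.28602763695324
P05,120.0,148.3747001697849
P05,140.0,189.37088081890388
P05,160.0,196.15644882210876
P06,60.0,56.16329451821853
P06,80.0,88.2723059707305
P06,100.0,103.7486452172972
P06,120.0,119.68334588947175
P06,140.0,151.46476674999755
P06,160.0,145.6612098343987
P06,60.0,47.565812351003395
P06,80.0,65.41467080427088
P06,100.0,91.49943472659373
P06,120.0,102.34777382241357
P06,140.0,143.18324730594597
P06,160.0,155.32661340663947
P06,60.0,39.25526473347429
P06,80.0,64.52463940625071
P06,100.0,98.53267123265337
P06,120.0,124.49590097692047
P06,140.0,156.7990467547198
P06,160.0,186.68746503770052
P07,60.0,30.120355218512508
P07,80.0,70.1597801691365
P07,100.0,75.39510211246741
P07,120.0,95.41278798364637
P07,140.0,109.4872401147177
P07,160.0,130.24214676102446
P07,60.0,62.10062033370204
P07,80.0,69.05315122015159
P07,100.0,81.93816469518379
P07,120.0,89.2098230571851
P07,140.0,98.8613786582722
P07,160.0,126.78697653445501
P07,60.0,50.902992517642396
P07,80.0,85.16196468149697
P07,100.0,84.82725828029953
P07,120.0,109.3937556956738
P07,140.0,110.61525211992425
P07,160.0,119.80061796101808
P08,60.0,64.86105045206364
P08,80.0,52.461582077325104
P08,100.0,86.15943664878941
P08,120.0,85.84436857241269
P08,140.0,121.28846622388238
P08,160.0,132.9213414980555
P08,60.0,42.00997415113108
P08,80.0,60.26782360821463
P08,100.0,71.22666765713207
P08,120.0,99.33436236810375
P08,140.0,107.42290129173213
P08,160.0,116.81577419932441
P08,60.0,30.7969773845158
P08,80.0,62.40132804679016
P08,100.0,93.56545717553031
P08,120.0,96.47355648901734
P08,140.0,110.78635283404111
P08,160.0,131.93009323302232
P09,60.0,68.9713316416835
P09,80.0,105.02102105607518
P09,100.0,119.12322834554784
P09,120.0,151.07075388634706
P09,140.0,158.42306834406165
P09,160.0,165.22356366009302
P09,60.0,59.39901195756423
P09,80.0,110.4674132777888
P09,100.0,132.0723211687647
P09,120.0,133.91800183356114
P09,140.0,152.7588507604827
P09,160.0,192.08269689972005
P09,60.0,62.010147129585995
P09,80.0,85.01086376591803
P09,100.0,121.26893190782215
P09,120.0,131.76714273779123
P09,140.0,156.53950530464186
P09,160.0,175.83382499205288
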