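# pacsense signal: test_signal_n300
# N: 300
# kind: harmonic_mixture
# components: 4
# snr_db: 25.0
# seed: 3
0.14930796929605572
0.16924148943313377
0.20349676520779536
0.24517898792451426
0.27463619035058845
0.2699601987359126
0.24930331682063064
0.19109896577047358
0.13020832745711824
0.08103431644095269
0.033287698645284865
0.009784452910314788
0.018680307298092603
0.04545982236359163
0.07827628701679187
0.07665200666878405
0.06668854736535236
0.039581952647795536
-0.025836622598291212
-0.08252399696333935
-0.1273555024311373
-0.160299755630329
-0.1668580091759852
-0.14104920097840018
-0.12415972089195654
-0.059589121269929574
-0.04296585952383889
-0.03994936508559082
-0.04398148232357519
-0.07466743185008001
-0.11993595377467163
-0.15244136489386415
-0.15282956190931535
-0.13387837505100345
-0.08183854746990903
-0.029791387228894343
0.02141570886733463
0.06617384708225163
0.07247166319544862
0.05656193026602922
0.035417362426410214
-0.001425153497184237
-0.03523203205297833
-0.048435676144718394
-0.02823198121704896
-0.011311718913362407
0.05109110435523703
0.0870687581965776
0.09225335213772144
0.09435791009568453
0.05289357046209482
0.009775365698435366
-0.06640839686719834
-0.10893489237238546
-0.12779234250951244
-0.1293222914122755
-0.1336772019320263
-0.09775144348950748
-0.07150552843712957
-0.07315673284454326
-0.0791406783995657
-0.13840522338621236
-0.18436938466322256
-0.24812644630845931
-0.2731375792972332
-0.2968877554922661
-0.2856336947122631
-0.25736012500259126
-0.18821909684890129
-0.1486984609631743
-0.118647942717137
-0.10786130920436562
-0.12437835572372637
-0.15316269475696365
-0.1744110939287974
-0.17881031953344861
-0.14496161776125938
-0.11573586241006921
-0.043951008453470476
0.031200244104608307
0.100203369761725
0.1478473252389942
0.15587811146126973
0.1481523554626277
0.13935525699862203
0.12612602017404217
0.11428003664092541
0.12196348126606255
0.15057478598287333
0.20013334062473806
0.24388013027213518
0.2846567266842175
0.28495175024924246
0.27254446485174155
0.22811639330882214
0.1751441808350543
0.11634222170237232
0.08750901999064642
0.059752760779787376
0.06118927421299636
0.05651749987992153
0.0877765331077325
0.09706050320860724
0.09524616624302902
0.045872382986302786
0.016782042835556767
-0.04162594751816062
-0.10708871549627573
-0.13619496485851798
-0.13923893948996166
-0.11170783239748111
-0.06734444447196225
-0.012647803240552627
0.011006930380874275
0.03594929663096422
0.029292971508358537
0.019029447801016546
-0.014037830763399756
-0.03017749825423549
-0.047073177471838666
-0.019318323223661123
0.02123500448448975
0.09294454111733622
0.14447551651552967
0.18096806473767907
0.19858389180000752
0.19649400940973924
0.16015584190268614
0.119907936048568
0.09353496287550406
0.08582049250614222
0.06979232088823972
0.08727127009078567
0.11257962832028827
0.13750632613394767
0.1591781275249171
0.14743608496978944
0.10357438575865809
0.04863867763339673
-0.015734598193982655
-0.07078580604366683
-0.1171098258601933
-0.12216859861570917
-0.10842281908140505
-0.0910555262005926
-0.06643259854904893
-0.0582581726579251
-0.06502089977253864
-0.08800368131545198
-0.1398515395916579
-0.18412955063965586
-0.21255867464132197
-0.22638938089258806
-0.20716740970198105
-0.19606950470353818
-0.131688620236672
-0.09555945808158246
-0.061405929379040394
-0.04820586426713016
-0.059505416235035
-0.08726019559682527
-0.12303610213697694
-0.13438907440803
-0.14696185729552322
-0.12430431515678386
-0.07832515736848598
-0.03846371405614365
0.021503456242032978
0.04097550093360491
0.05156879940289142
0.019109197640839758
-0.016409247643766882
-0.04851893509134612
-0.0699121594600965
-0.083144472354821
-0.059634931378932894
-0.02658968412700414
0.02655168368211404
0.05020147049325021
0.08211195631338283
0.07081713539073187
0.04723983705652993
0.014508458853647061
-0.02321145658699444
-0.03784963202367932
-0.03497733460202298
-0.02077717398303411
0.0184458066335888
0.06702034421006162
0.09401795805421784
0.11127427216399562
0.10312461891916475
0.06860637494902344
0.04441187665480068
-0.010324823021617012
-0.022853587811469775
-0.034646562689238665
-0.014072655998189104
0.0076340724808496956
0.036869150937714375
0.07048032899679266
0.073491370454115
0.06257774773149666
0.03153056330807327
-0.012095375984785274
-0.05260919000193284
-0.08249365640463965
-0.08254549579332206
-0.07587088124679973
-0.02816604301250547
0.006576419727342071
0.05545536736237993
0.07451176518646649
0.052274878374320315
0.04543879114374774
0.015412574682579972
-0.015190887245333757
-0.01579944738843067
-0.011207838841113742
0.012405239045477228
0.0674264448612192
0.11641107691756403
0.15621630690776275
0.16653719338671458
0.17322433582930577
0.1492000126553178
0.10192473828381841
0.07041311227521675
0.05149486020042307
0.04432445599988673
0.0724403410290233
0.08792403957337726
0.10540736837541721
0.12010038724137793
0.11768835811520865
0.10255580494928518
0.039225811549350294
-0.01521447034633696
-0.06492714888613915
-0.10509891317273111
-0.10583723271176237
-0.11711221160806574
-0.08876818671675367
-0.0685848069857192
-0.050053758326915825
-0.06175606724046398
-0.0625414743710477
-0.10708136413741262
-0.1429714522262168
-0.17785977295896543
-0.18731002701693722
-0.1667043332810757
-0.12979236393024451
-0.08318116717790491
-0.030355484067761392
0.006571469883492235
0.023869953534940553
0.029666130324664898
0.012635133625922262
-0.01393684124534689
-0.02632782682353692
-0.025951331274320526
-0.016555701828040875
0.012598519424862047
0.06085735879683739
0.10698772459403166
0.11857472512839345
0.12225517197450991
0.10198694887076476
0.07291648271421008
0.009484902368783058
-0.016240594921853452
-0.035272800929358875
-0.05179216579930122
-0.023478107007978526
-0.0049170370855839834
0.012106087366954926
0.02902107196074468
0.012240480535443672
-0.006654665779203956
-0.029686610483418672
-0.08669725096763317
-0.10037005414039098
-0.12387164528217129
-0.10580229517137874
-0.08005717095066381
-0.051024468793167355
0.002195223923554547
0.03830657105243132
0.04278743971498984
0.034909465343110596
0.025046063814092103
-0.005334803669648614
-0.028231195943340552
-0.022015568098746732
0.007072364808248721
0.03447594542529382
0.08590004005530234
0.12746722820793704
0.14041252974941065
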