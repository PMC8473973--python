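-0.6264538107423324176
 0.1836433242220822382
-0.8356286124100471557
 1.5952808021377915537
 0.3295077718153605062
-0.8204683841180152593
 0.4874290524284852766
 0.7383247051292173291
 0.5757813516534923126
-0.3053883871563560226
 1.5117811684508479786
 0.3898432364114310933
-0.6212405805418037552
-2.2146998871774998818
 1.1249309181431081939
-0.0449336090152308507
-0.0161902630989460873
 0.9438362106852992151
 0.8212211950980885522
 0.5939013212175088263
 0.9189773716082182409
 0.7821363007310671023
 0.0745649833651906013
-1.9893516958633727931
 0.6198257478947102328
-0.0561287395290007846
-0.1557955067053292952
-1.4707523838992744292
-0.4781500551086203532
 0.4179415601997024110
 1.3586795515290439607
-0.1027877273429955163
 0.3876716115593691336
-0.0538050405829051184
-1.3770595568286065902
-0.4149945632996797640
-0.3942899537103493057
-0.0593133967111856633
 1.1000253719838830602
 0.7631757484575442119
-0.1645235962535868957
-0.2533616801365075610
 0.6969633754047374063
 0.5566631986736573223
-0.6887556945495199034
-0.7074951569621196201
 0.3645819621368303065
 0.7685329245154157718
-0.1123462121502280531
 0.8811077264542147569
 0.3981058803670680657
-0.6120263932507712390
 0.3411196914244247758
-1.1293630960807925501
 1.4330237017010369893
 1.9803998985058599569
-0.3672214764665090447
-1.0441346263165307562
 0.5697196274424128903
-0.1350546038808243532
 2.4016177605047763777
-0.0392400027331692436
 0.6897393624507767163
 0.0280021587806660623
-0.7432732088824053340
 0.1887922995143428984
-1.8049586288910377530
 1.4655548615628859466
 0.1532533382118977106
 2.1726116703621527471
 0.4755095288996625258
-0.7099464309218145308
 0.6107263534890549073
-0.9340976316442515248
-1.2536334002391020803
 0.2914462355174628483
-0.4432918732184329969
 0.0011053516316241311
 0.0743413241516640566
-0.5895209461880719370
-0.5686687328185019430
-0.1351786151238320577
 1.1780869965732043703
-1.5235668004297620026
 0.5939461876284215514
 0.3329503712135182814
 1.0630998372763627025
-0.3041839236343006347
 0.3700188099162881605
 0.2670987907722310317
-0.5425200309916503594
 1.2078678059831722269
 1.1604026156949516224
 0.7002136495149982043
 1.5868334545408455671
 0.5584864255653039233
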