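{
  "seed0": [
    0.9911880259201318,
    1.0580547847529969,
    0.922555740708153,
    1.0172260367646002,
    1.0243848804772688,
    0.9918878132039836
  ],
  "seed1": [
    0.9285280432245798,
    1.06957745922327,
    1.0232204194547767,
    1.0105119155519915,
    0.9449540865715809,
    1.0305555075714716
  ],
  "seed2": [
    1.01599812101152,
    0.9947556974555108,
    1.0018170364109638,
    0.9355592593484209,
    0.9959434856409883,
    1.059976533117732
  ],
  "seed3": [
    0.9608958423645163,
    1.057744419649424,
    1.0428748319031778,
    1.0405662305426178,
    0.9140561230111777,
    0.9919006308659734
  ],
  "seed4": [
    0.9335911760882991,
    1.0491654470968443,
    0.9392157634044408,
    0.9416886000318164,
    1.0708350312801098,
    1.07796342675685
  ],
  "seed5": [
    0.990509746252335,
    0.966124190890186,
    1.0268593955676468,
    0.9754002436340157,
    0.9922655230253183,
    1.051444969591276
  ],
  "seed6": [
    0.9867881195036614,
    1.0035891306967981,
    1.066482570362665,
    0.9972059182764009,
    0.9101384154026353,
    1.0432156264053551
  ],
  "seed7": [
    1.0251340252024663,
    1.0255603293552649,
    0.9776782968411976,
    0.9827539126098419,
    0.9835154329483924,
    1.0065519702203605
  ],
  "seed8": [
    0.9248684273311396,
    1.040499599541389,
    1.0396040562994144,
    1.0536758308993799,
    1.000035869933647,
    0.9486097127801615
  ],
  "seed9": [
    1.0177961774860123,
    0.9066528127223771,
    0.9196228783960183,
    1.0369674704055338,
    1.1254745644612136,
    1.0096889117360572
  ],
  "seed10": [
    0.9866778163876105,
    1.0067200289715994,
    0.943073768477976,
    0.9887021488667732,
    0.9729948555701751,
    1.1096710082097672
  ],
  "seed11": [
    1.0406957921409472,
    0.9804234251145227,
    0.9727944990332524,
    0.9492599013399681,
    1.003880396731524,
    1.057241754368709
  ],
  "seed12": [
    1.030551145034334,
    0.9711137008271121,
    0.9748019778523339,
    0.9984581629626635,
    0.9947618407749834,
    1.0320363106101538
  ],
  "seed13": [
    1.0545580940762438,
    1.029443280428621,
    0.9456278792697831,
    1.034549907601012,
    0.9209200974856532,
    1.0224295731303024
  ],
  "seed14": [
    1.0019194102087647,
    0.9912316945452281,
    0.9822144620768702,
    1.033917877223556,
    0.9582740365477167,
    1.0346892548638535
  ],
  "seed15": [
    0.9361592750365658,
    0.9626201815244718,
    1.1093102709631737,
    0.9622813447321205,
    1.02800557588518,
    1.0112178385844628
  ],
  "seed16": [
    1.0186814707270453,
    1.0910652450341645,
    1.019140583451576,
    0.9319183096491237,
    1.0343660000356345,
    0.9158507262665316
  ],
  "seed17": [
    0.9760364335728592,
    1.04261659396486,
    0.9850843452077759,
    1.0548128740750304,
    0.9265119670139276,
    1.0207266777037158
  ],
  "seed18": [
    0.9656815244097183,
    1.0236840504434541,
    1.0298358932211273,
    1.012517373800828,
    1.0578120608474058,
    0.9171093432391444
  ],
  "seed19": [
    1.0313345733586265,
    0.9732400413394102,
    1.0514367679293546,
    0.9269252396329684,
    1.048050328884384,
    0.9753723686517918
  ]
}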