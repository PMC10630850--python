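component,property,c0,c1,c2
water,density,997.18,3.1439e-3,-3.7574e-3
protein,density,1329.9,-0.51840,0.0
fat,density,925.59,-0.41757,0.0
carbohydrate,density,1599.1,-0.31046,0.0
fiber,density,1311.5,-0.36589,0.0
ash,density,2423.8,-0.28063,0.0
water,specific_heat,4176.2,-9.0864e-2,5.4731e-3
protein,specific_heat,2008.2,1.2089,-1.3129e-3
fat,specific_heat,1984.2,1.4733,-4.8008e-3
carbohydrate,specific_heat,1548.8,1.9625,-5.9399e-3
fiber,specific_heat,1845.9,1.8306,-4.6509e-3
ash,specific_heat,1092.6,1.8896,-3.6817e-3
water,conductivity,0.57109,1.7625e-3,-6.7036e-6
protein,conductivity,0.17881,1.1958e-3,-2.7178e-6
fat,conductivity,0.18071,-2.7604e-4,-1.7749e-7
carbohydrate,conductivity,0.20141,1.3874e-3,-4.3312e-6
fiber,conductivity,0.18331,1.2497e-3,-3.1683e-6
ash,conductivity,0.32962,1.4011e-3,-2.9069e-6
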