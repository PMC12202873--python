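category,handle,organization,followers,posts
antiregulation,nra,National Rifle Association,917200,16527
antiregulation,gunowners,Gun Owners of America,333500,8463
antiregulation,gunpolicy,Firearms Policy Coalition,215500,12519
antiregulation,usacarry,USA Carry,86600,34849
antiregulation,natlgunrights,National Association for Gun Rights,64800,6356
antiregulation,uscca,US Concealed Carry Association,64800,49746
antiregulation,blkgunsmattr,Black Guns Matter,43500,4279
antiregulation,bearingarmscom,BearingArms.com,25300,22238
antiregulation,naaganational,National African American Gun Association,14800,405
proregulation,amarch4ourlives,A March for our Lives,440400,25866
proregulation,momsdemand,Moms Demand Action,343600,37289
proregulation,everytown,Everytown USA,267600,21739
proregulation,giffordscourage,Giffords,104700,17326
proregulation,bradybuzz,Brady: United Against Gun Violence,76800,15316
proregulation,newtownaction,Newtown Action Alliance,46400,21562
proregulation,csgv,Coalition to Stop Gun Violence,36800,58865
proregulation,protesteasyguns,Protest Easy Guns,8797,24462
proregulation,efsgv,Educational Fund to Stop Gun Violence,3830,2511
proregulation,gunsdownamerica,Guns Down America,15000,2599
proregulation,wagv,Women Against Gun Violence,22500,10951
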