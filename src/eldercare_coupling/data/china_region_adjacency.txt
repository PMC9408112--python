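Beijing,Tianjin
Beijing,Hebei
Tianjin,Hebei
Hebei,Shanxi
Hebei,Inner Mongoria
Hebei,Liaoning
Hebei,Shandong
Hebei,Henan
Shanxi,Inner Mongoria
Shanxi,Shaanxi
Shanxi,Henan
Inner Mongoria,Heilongjiang
Inner Mongoria,Jilin
Inner Mongoria,Liaoning
Inner Mongoria,Shaanxi
Inner Mongoria,Ningxia
Inner Mongoria,Gansu
Liaoning,Jilin
Jilin,Heilongjiang
Shanghai,Jiangsu
Shanghai,Zhejiang
Jiangsu,Shandong
Jiangsu,Anhui
Jiangsu,Zhejiang
Zhejiang,Anhui
Zhejiang,Jiangxi
Zhejiang,Fujian
Anhui,Shandong
Anhui,Henan
Anhui,Hubei
Anhui,Jiangxi
Fujian,Jiangxi
Fujian,Guangdong
Jiangxi,Guangdong
Jiangxi,Hunan
Jiangxi,Hubei
Shandong,Henan
Henan,Shaanxi
Henan,Hubei
Hubei,Shaanxi
Hubei,Chongqing
Hubei,Hunan
Hunan,Chongqing
Hunan,Guizhou
Hunan,Guangxi
Hunan,Guangdong
Guangdong,Guangxi
Guangdong,Hainan
Guangxi,Yunnan
Guangxi,Guizhou
Chongqing,Sichuan
Chongqing,Shaanxi
Chongqing,Guizhou
Sichuan,Qinghai
Sichuan,Gansu
Sichuan,Shaanxi
Sichuan,Guizhou
Sichuan,Yunnan
Sichuan,Tibet
Guizhou,Yunnan
Yunnan,Tibet
Tibet,Xinjiang
Tibet,Qinghai
Shaanxi,Gansu
Shaanxi,Ningxia
Gansu,Xinjiang
Gansu,Qinghai
Gansu,Ningxia
Qinghai,Xinjiang
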